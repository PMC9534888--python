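# ctcenter

Quality-assurance toolkit for **vertical patient centering in pediatric
chest CT**. It answers, with simulated cohorts and reusable measurement
code, the question a radiology physics team asks when small children are
scanned on stacked positioning pads: *how far does the patient's center sit
from the gantry isocenter, and does setting the table height from a
pre-scan chest-thickness measurement beat manual positioning?*

Off-center positioning matters because tube-current modulation estimates
patient size from the scout view and the bowtie filter shapes the beam
around the isocenter: a child lying low gets a dose and noise penalty. The
package implements:

* **`phantom`** — synthetic cohorts of pediatric thorax phantoms (elliptical
  body on a −900 HU pad slab, aortic contrast inserts, Gaussian noise) with
  exact ground-truth vertical offsets, chest/width geometry, ruler
  measurement bias, pad dent and CTDIvol.
* **`centering`** — the image-side measurement: HU-threshold segmentation,
  per-slice skin-surface midpoints, the scan-averaged center, the signed
  isocenter distance `d = (iso_row − center_row) · 354/512` mm (positive
  above), body thickness `T` and width `W`, the distance ratio `d/T`, a
  >20 mm flag, and a pad-thickness estimate `table_height + d − T/2`.
* **`positioning`** — the table-height rule `height = 75 + chest/2` (mm),
  its 100 mm hardware-limit feasibility check, and the predicted offset for
  imperfect measurements and dented pads.
* **`dosimetry`** — effective diameter `√(T·W)`, SSDE via the standard
  exponential conversion-factor fit (16/32 cm reference phantoms), DLP.
* **`quality`** — circular-ROI SNR (`mean/SD`) and dose-normalized SNR
  (`SNR/√dose`) at the aortic insert positions.
* **`stats`** — mean±SD / median[IQR] summaries with normal-approximation
  CIs and Shapiro–Wilk annotation, an exact-enumeration rank-sum test,
  uncorrected Pearson χ² for 2×2 tables, and Pearson correlation.
* **`pipeline` / `cli`** — the end-to-end `simulate → measure → dose /
  quality → compare` driver and a `ctcenter` command with subcommands
  `simulate`, `measure`, `plan`, `dose`, `quality`, `compare`, `run`.

See `docs/methods.md` for the model, the synthetic-cohort calibration, and
every numerical convention.

## Worked example

```python
import numpy as np
from ctcenter import (CohortSpec, sample_cohort, render_volume, measure,
                      dose_report, set_table_height)

spec = CohortSpec(n_patients=3, seed=1, noise_sd=10.0)   # calculated-group defaults
for p in sample_cohort(spec):
    vol = render_volume(p, spec=spec, rng=np.random.default_rng(p.patient_id))
    res = measure(vol, threshold=-250.0)
    print(f"true {p.true_offset:+6.2f} mm  measured {res.isocenter_distance:+6.2f} mm  "
          f"T {res.body_thickness:5.1f} mm  pad {res.pad_thickness_estimate:4.1f} mm")
```

prints

```
true  -4.34 mm  measured  -4.18 mm  T 103.6 mm  pad 74.9 mm
true  -1.29 mm  measured  -1.44 mm  T 111.9 mm  pad 72.0 mm
true  +0.25 mm  measured  +0.10 mm  T 103.9 mm  pad 73.3 mm
```

— the full segmentation-and-averaging chain recovers each phantom's true
vertical offset to well under one pixel (0.69 mm), and the back-calculated
pad thickness reflects each patient's sampled pad dent. Planning side:

```python
>>> set_table_height(108.7)      # mm below isocenter, for a 108.7 mm chest
129.35
>>> dose_report(ctdivol=0.72, thickness_mm=104, width_mm=152,
...             scan_length_mm=120, phantom=32).ssde
1.6809...  # mGy: a 12.6 cm child absorbs ~2.3x the 32 cm-phantom CTDIvol
```

A complete two-group study (34 manually positioned vs 33 formula-positioned
patients, offsets drawn from their observed distributions) runs with

```bash
ctcenter run --out study/ --seed 7
```

and writes `results.csv` (one row per patient: ground truth, centering,
dose, SNR) and `comparison.json` (rank tests per metric plus the χ² on the
>20 mm off-centering proportions).

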