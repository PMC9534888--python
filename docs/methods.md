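# Methods

## Problem and model

When a CT patient lies above or below the gantry isocenter, the automated
tube-current modulation misjudges patient size from the scout view and the
bowtie filter attenuates the periphery of the field, degrading image quality
or raising dose. In small children the problem is acute: the body is small,
an immobilization vacuum device hides the body outline, and pads are stacked
on the table to lift the child toward the isocenter.

`ctcenter` models the positioning workflow in which a high-resilience pad
system of nominal thickness 75 mm lies on the table and the table height
(the scanner-reported distance from isocenter down to tabletop) is set from
a pre-scan ruler measurement of chest thickness:

    set table height = 75 + chest thickness / 2        [mm]

With the patient's center `pad + chest/2` above the tabletop, this places the
center at the isocenter. Two error sources propagate through this chain with
known sensitivities:

* a chest-thickness measurement error Δ moves the patient by −Δ/2
  (`positioning.predicted_offset`);
* a pad dent δ (the body sinking into the pad) moves the patient by −δ.

The signed vertical offset `d` (positive above isocenter) is measured from
the reconstructed images: each axial slice is binarized at an HU threshold,
the body component kept, the per-slice center defined as the midpoint
between the highest and lowest skin rows, the centers averaged along the
scan, and the row offset from the isocenter converted to mm through the
pixel pitch (354 mm DFOV / 512 matrix = 0.6914 mm per pixel; reconstructions
are assumed centered on the isocenter). Derived quantities: averaged AP body
thickness `T`, middle-slice lateral width `W`, distance ratio `d/T·100` (%),
a >20 mm off-centering flag, and a back-calculated pad thickness

    pad = table height + d − T/2,

which holds exactly when the lowest skin point rests on the pad top.

Dosimetry follows the standard size-specific dose estimate: effective
diameter `D = sqrt(T·W)` in cm and `SSDE = a·exp(−b·D)·CTDIvol` with the
published exponential-fit coefficients for the 32 cm (a=3.704369,
b=0.03671937) or 16 cm (a=1.874799, b=0.03871313) reference phantom, valid
for 6–55 cm. The exponential fit is used instead of the tabulated factors;
the two agree within the report's own tolerance and the fit is analytically
testable (monotonicity, the unity crossover at D = ln(a)/b ≈ 35.67 cm for
the 32 cm phantom). Image quality is ROI-based: `SNR = mean/SD` of HU in a
circular aortic ROI, and `SNRD = SNR/√dose`.

## Synthetic cohorts

No patient images ship with this package; every analysis runs on synthetic
phantoms with exact ground truth (`phantom` module).

A cohort draw samples, per patient: true chest thickness ~ N(104, 17) mm,
body width ~ N(152, 44.5) mm (location = clinical medians, scale = IQR/1.349,
truncated to physically renderable ranges), scan length ~ N(120, 20) mm,
ruler bias ~ N(7.2, 10.25) mm (added to the true thickness to give the ruler
value), pad dent ~ N(3.4, 4.1) mm, and CTDIvol lognormal with median 0.72
and IQR 0.52 mGy (σ = asinh(IQR/2m)/z₀.₇₅, which matches both the median and
the IQR exactly). The bias and dent SDs are back-derived from 95% CIs at
n = 33 (half-width = 1.96·SD/√33). All sampling and rendering noise flow
from a single integer seed through `numpy.random.default_rng`; identical
seeds give bit-identical cohorts and volumes.

The true offset is assigned in one of two modes:

* **direct** — drawn from a configured normal distribution; the defaults
  are the observed per-group distributions (calculated 0.2 ± 5.8 mm,
  manual −8.3 ± 11.6 mm). Used for recovery experiments.
* **mechanistic** — `(75 − dent) + true_chest/2 − set_table_height(ruler)`,
  i.e. the offset the table-height formula actually produces given the
  sampled bias and dent. With the mean reported inputs (dent 3.4 mm, true
  101.5 mm, ruler 108.7 mm) this identity gives −7.0 mm. Note the observed
  calculated-group mean is +0.2 mm, not −7.0 mm: the reported chest-thickness
  overestimate and pad dent, pushed through the geometry, predict a lower
  patient than observed (plausibly because the nipple-level ruler thickness
  and the scan-averaged CT thickness are different quantities, or because
  the errors are correlated). The simulator exposes both modes and does not
  resolve this; recovery targets use the direct mode.

Rendering: the thorax is a stack of soft-tissue ellipses (0 HU) in air
(−1000 HU). The AP diameter follows a sine window along z, tapering to 85%
of the thickest-slice value at the scan ends, so the averaged CT thickness
sits below the nipple-level maximum — the direction of the clinical
ruler-vs-CT gap. All slices share the bottom (pad-contact) row; the stack is
placed so the mean of the per-slice midpoints sits exactly `true_offset`
above the isocenter row. A −900 HU pad slab of the dented thickness lies
directly beneath the body, and two 6 mm-radius circular inserts at the
configured aorta HU (default 400, giving SNR ≈ 40 at the default 10 HU
noise) are drawn on the middle ("tracheal bifurcation") slice. White
Gaussian noise (default SD 10 HU) is added to every voxel. The stored table
height is derived from the scene (`pad_actual + mean_AP/2 − true_offset`),
so the pad identity holds by construction.

What the phantom does *not* emulate: internal anatomy (lungs, spine,
mediastinum), arms or cables in the field, scanner physics (tube-current
modulation, bowtie filtration, beam hardening, streak or motion artifacts),
and non-elliptical body contours. Passing recovery tests therefore
demonstrates the correctness of the measurement chain and its statistical
behavior under the stated geometry — not robustness to real-world
segmentation hazards such as arms inside the field of view.

## Numerical choices

* **HU threshold −250** (configurable): separates soft tissue/skin from the
  foam pad (−900) and air (−1000). No threshold is prescribed clinically;
  anything in (−500, −150) behaves identically on these phantoms.
* **Body selection**: per slice, 8-connected components touching the bottom
  image border (table remnants) are discarded, then the largest component is
  kept. Slices with no remaining component are flagged empty, logged, and
  excluded from averages; an all-empty volume is an error.
* **Sub-pixel convention**: voxel centers at integer coordinates; extents
  counted inclusively, so a single-voxel body is one pixel pitch thick.
  Per-slice centers are `(min_row + max_row)/2`, exact to half a pixel.
* **Middle slice** for the width measurement is `floor(n/2)` (0-based),
  falling back to the nearest non-empty slice.
* **Distance ratio** is signed by default (an absolute variant is a flag),
  matching the signed summary convention of the offset itself.
* **Rank test**: exact enumeration of the rank-sum null (midranks under
  ties) for combined n ≤ 20; tie-corrected normal approximation above.
  The between-group default is the unpaired rank-sum test; a signed-rank
  test is exposed separately for genuinely paired data.
* **χ² 2×2** is the uncorrected Pearson statistic — with Yates correction
  the 4/30 vs 0/33 off-centering table gives p ≈ 0.13 instead of the
  ≈ 0.04 obtained without it — and raises on zero margins.
* **95% CI** convention: mean ± 1.96·SD/√n (normal approximation).
* **SNRD normalization** defaults to CTDIvol, configurable to SSDE; the
  choice is recorded in every output.
* **Table limit**: a required table height below the 100 mm hardware limit
  warns rather than errors, since scanner behavior at the limit is not
  modeled.

## Problem sizes

Unit tests run on short-scan phantoms (20–60 mm scans, 4–12 slices) at the
full 512×512 matrix. The cohort-recovery experiment
(`pipeline.offset_recovery_experiment`, also driven by
`scripts/acceptance.py`) uses 50 replicate cohorts of 33 phantoms at default
geometry — 1650 rendered and measured volumes, a few minutes on one CPU —
and accepts the recovered mean and SD within 3 standard errors computed
across replicates.

## Known limitations

* Vertical centering only; lateral off-centering is not measured.
* Geometric effective diameter only (no water-equivalent diameter).
* The phantom's aorta inserts are geometric stand-ins; SNR magnitudes match
  the clinical range by construction of the noise model, not by physics.
* The reference-phantom size for SSDE must be stated explicitly (16 vs
  32 cm) because scanner conventions differ; nothing is inferred.
* No multiple-testing adjustment in the comparison layer.
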