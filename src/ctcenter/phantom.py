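"""Synthetic pediatric chest-CT phantom cohorts with known positioning ground truth.

The generator emulates the study population this package analyzes: young
children positioned supine on a 75 mm high-resilience pad system inside the
CT gantry.  Each synthetic patient carries a true chest thickness, a
ruler-measured chest thickness (true value plus a measurement bias), a body
width, a pad dent, a dose output (CTDIvol) and a signed vertical offset of
the body center from the gantry isocenter.  Axial volumes are rendered as a
stack of soft-tissue ellipses on a low-HU pad slab, with two
contrast-enhanced aortic inserts at the tracheal-bifurcation slice, so the
full measurement pipeline can be exercised against exact ground truth.

Two offset modes are provided:

``direct``
    The true offset is drawn from a configured normal distribution (the
    reported per-group offset distributions).  Used for recovery studies.

``mechanistic``
    The offset follows from the positioning geometry: the patient rests on
    a (possibly dented) pad, and the table is set from the *ruler* chest
    thickness, so measurement bias and pad dent propagate into the offset::

        offset = (pad_nominal - pad_dent) + true_chest/2 - set_table_height(ruler_chest)

    Used for sensitivity studies of the table-height formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .positioning import set_table_height
from .volume import CTVolume

__all__ = [
    "CohortSpec",
    "PatientModel",
    "sample_cohort",
    "apply_positioning",
    "render_volume",
]

# Upper quartile of the standard normal; converts an IQR into a normal or
# lognormal scale parameter.
_Z75 = 0.674489750196082


@dataclass
class CohortSpec:
    """Distributional description of one synthetic patient group.

    Location/scale defaults follow the study's cohort tables: body (chest)
    thickness median 104 mm with IQR 96–119 mm and body width median 152 mm
    with IQR 113–173 mm, converted to normal parameters via
    ``sd = IQR / 1.349``.  The ruler-vs-CT chest-thickness bias (mean 7.2 mm)
    and pad dent (mean 3.4 mm) use SDs back-derived from the printed 95%
    confidence intervals at n = 33.  CTDIvol is lognormal, parameterized by
    its median and IQR (0.72 and 0.52 mGy).

    ``direct_offset_dist`` defaults to the calculated group's reported
    offset distribution (0.2 ± 5.8 mm); use (-8.3, 11.6) for a manual-style
    group.
    """

    n_patients: int = 33
    group_label: str = "calculated"
    seed: int = 0
    chest_thickness_dist: tuple[float, float] = (104.0, 17.0)
    body_width_dist: tuple[float, float] = (152.0, 44.5)
    scan_length_dist: tuple[float, float] = (120.0, 20.0)
    offset_mode: str = "direct"
    direct_offset_dist: tuple[float, float] = (0.2, 5.8)
    ruler_bias_dist: tuple[float, float] = (7.2, 10.25)
    pad_dent_dist: tuple[float, float] = (3.4, 4.1)
    ctdivol_dist: tuple[float, float] = (0.72, 0.52)  # (median, IQR), mGy
    aorta_hu: float = 400.0
    body_hu: float = 0.0
    pad_hu: float = -900.0
    noise_sd: float = 10.0
    pad_nominal: float = 75.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.offset_mode not in ("direct", "mechanistic"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")
        for name in (
            "chest_thickness_dist",
            "body_width_dist",
            "scan_length_dist",
            "direct_offset_dist",
            "ruler_bias_dist",
            "pad_dent_dist",
            "ctdivol_dist",
        ):
            loc, scale = getattr(self, name)
            if scale < 0:
                raise ValueError(f"{name}: scale must be >= 0, got {scale}")
        if self.ctdivol_dist[0] <= 0:
            raise ValueError("ctdivol_dist median must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pad_nominal <= 0:
            raise ValueError("pad_nominal must be positive")


@dataclass
class PatientModel:
    """Ground truth and measured quantities for one synthetic patient.

    ``true_offset`` is the signed vertical distance (mm) of the patient's
    averaged center from the gantry isocenter, positive above.
    """

    true_chest_thickness: float  # mm, AP extent at the thickest slice
    ruler_chest_thickness: float  # mm, true + sampled measurement bias
    body_width: float  # mm, lateral extent
    scan_length: float  # mm
    pad_nominal: float  # mm
    pad_dent: float  # mm
    true_offset: float  # mm, signed (up = positive)
    ctdivol: float  # mGy
    group_label: str = "calculated"
    patient_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pad_nominal - self.pad_dent <= 0:
            raise ValueError("pad_nominal - pad_dent must be positive")
        if self.ruler_chest_thickness <= 0:
            raise ValueError("ruler_chest_thickness must be positive")

    @property
    def pad_actual(self) -> float:
        """Actual (dented) pad thickness under load, mm."""
        return self.pad_nominal - self.pad_dent


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = -np.inf,
    high: float = np.inf,
) -> np.ndarray:
    """Normal draws with out-of-range values resampled (rejection)."""
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    # sd == 0 degenerates to the mean; a mean outside the range is a caller bug
    while bad.any():
        if sd == 0:
            raise ValueError(f"degenerate mean {mean} outside ({low}, {high})")
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def _lognormal_from_median_iqr(
    rng: np.random.Generator, median: float, iqr: float, size: int
) -> np.ndarray:
    # Lognormal quartiles are median*exp(±z75*sigma), so
    # IQR = 2*median*sinh(z75*sigma) and sigma has a closed form.
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75 if iqr > 0 else 0.0
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def apply_positioning(
    patient: PatientModel,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Return the signed true vertical offset (mm) for one patient.

    In ``direct`` mode the offset is a draw from ``spec.direct_offset_dist``.
    In ``mechanistic`` mode it is the deterministic consequence of setting
    the table from the ruler-measured chest thickness while the patient
    rests on the dented pad.
    """
    if spec.offset_mode == "direct":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        mean, sd = spec.direct_offset_dist
        return float(rng.normal(mean, sd))
    height = set_table_height(patient.ruler_chest_thickness, pad=patient.pad_nominal)
    return patient.pad_actual + patient.true_chest_thickness / 2.0 - height


def sample_cohort(spec: CohortSpec) -> list[PatientModel]:
    """Draw ``spec.n_patients`` synthetic patients.

    Deterministic under ``spec.seed`` (bit-identical cohorts for identical
    specs).  Chest thickness, width and scan length are truncated to
    physically meaningful ranges; the ruler measurement is the true chest
    thickness plus a bias draw.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    chest = _truncated_normal(rng, *spec.chest_thickness_dist, n, low=20.0, high=260.0)
    width = _truncated_normal(rng, *spec.body_width_dist, n, low=40.0, high=330.0)
    length = _truncated_normal(rng, *spec.scan_length_dist, n, low=20.0, high=400.0)
    bias = rng.normal(*spec.ruler_bias_dist, n)
    dent = _truncated_normal(
        rng, *spec.pad_dent_dist, n, low=-np.inf, high=spec.pad_nominal - 1.0
    )
    ctdivol = _lognormal_from_median_iqr(rng, *spec.ctdivol_dist, n)

    patients: list[PatientModel] = []
    for i in range(n):
        ruler = max(chest[i] + bias[i], 1.0)
        p = PatientModel(
            true_chest_thickness=float(chest[i]),
            ruler_chest_thickness=float(ruler),
            body_width=float(width[i]),
            scan_length=float(length[i]),
            pad_nominal=spec.pad_nominal,
            pad_dent=float(dent[i]),
            true_offset=0.0,
            ctdivol=float(ctdivol[i]),
            group_label=spec.group_label,
            patient_id=i,
        )
        p.true_offset = apply_positioning(p, spec, rng=rng)
        patients.append(p)
    return patients


def _ap_profile(ap_max: float, n_slices: int, floor_fraction: float) -> np.ndarray:
    """Per-slice AP diameters: a sine window scaled so the thickest slice
    equals ``ap_max`` and end slices taper to ``floor_fraction * ap_max``.

    The averaged thickness along the scan is therefore below the
    thickest-slice (nipple-level) thickness, mirroring the direction of the
    ruler-vs-CT thickness gap seen clinically.
    """
    if n_slices == 1:
        return np.array([ap_max])
    w = np.sin(np.pi * (np.arange(n_slices) + 0.5) / n_slices)
    w = w / w.max()
    return ap_max * (floor_fraction + (1.0 - floor_fraction) * w)


def render_volume(
    patient: PatientModel,
    true_offset: Optional[float] = None,
    *,
    spec: Optional[CohortSpec] = None,
    matrix: tuple[int, int] = (512, 512),
    dfov: float = 354.0,
    slice_spacing: float = 5.0,
    ap_floor_fraction: float = 0.85,
    aorta_radius: float = 6.0,
    rng: Optional[np.random.Generator] = None,
) -> CTVolume:
    """Render one patient as an axial HU volume with exact ground truth.

    The body is a stack of soft-tissue ellipses whose AP diameter varies
    smoothly along z (maximum = ``true_chest_thickness``); all slices rest
    on the pad, so the lowest skin row is shared.  The stack is placed so
    that the *mean of per-slice vertical midpoints* sits ``true_offset`` mm
    above the isocenter (up = decreasing row index).  A ``pad_hu`` slab of
    the actual (dented) pad thickness lies directly beneath the body, and
    two circular aortic inserts (ascending, descending) are drawn on the
    middle ("tracheal bifurcation") slice.  Gaussian noise of
    ``spec.noise_sd`` HU is added to every voxel.

    The stored ``table_height`` is derived from the geometry:
    ``pad_actual + mean_AP/2 - true_offset``, i.e. the tabletop distance
    below the isocenter consistent with the rendered scene.

    Raises ``ValueError`` naming the violated extent if the geometry does
    not fit the grid.
    """
    if spec is None:
        spec = CohortSpec(group_label=patient.group_label)
    if true_offset is None:
        true_offset = patient.true_offset
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    rows, cols = matrix
    pitch = dfov / cols
    n_slices = max(1, int(round(patient.scan_length / slice_spacing)))
    iso_r, iso_c = (rows - 1) / 2.0, (cols - 1) / 2.0

    ap = _ap_profile(patient.true_chest_thickness, n_slices, ap_floor_fraction)
    ap_mean = float(ap.mean())
    pad = patient.pad_actual

    # Lowest skin point (shared bottom row, continuous coordinate).
    bottom_row = iso_r - true_offset / pitch + ap_mean / (2.0 * pitch)
    top_row = bottom_row - ap.max() / pitch
    half_width_px = patient.body_width / (2.0 * pitch)
    left_col = iso_c - half_width_px
    right_col = iso_c + half_width_px

    if top_row < 0 or bottom_row > rows - 1:
        raise ValueError(
            f"body AP extent [row {top_row:.1f}, {bottom_row:.1f}] exceeds "
            f"grid rows [0, {rows - 1}]"
        )
    if left_col < 0 or right_col > cols - 1:
        raise ValueError(
            f"body width extent [col {left_col:.1f}, {right_col:.1f}] exceeds "
            f"grid columns [0, {cols - 1}]"
        )

    hu = np.full((n_slices, rows, cols), -1000.0, dtype=np.float32)
    rx = half_width_px

    for k in range(n_slices):
        ry = ap[k] / (2.0 * pitch)
        cy = bottom_row - ry
        r0, r1 = max(0, math.ceil(cy - ry)), min(rows - 1, math.floor(cy + ry))
        c0, c1 = max(0, math.ceil(iso_c - rx)), min(cols - 1, math.floor(iso_c + rx))
        rr = np.arange(r0, r1 + 1, dtype=np.float64)[:, None]
        cc = np.arange(c0, c1 + 1, dtype=np.float64)[None, :]
        inside = ((rr - cy) / ry) ** 2 + ((cc - iso_c) / rx) ** 2 <= 1.0
        block = hu[k, r0 : r1 + 1, c0 : c1 + 1]
        block[inside] = spec.body_hu

    # Pad slab directly beneath the body bottom, full image width.
    pad_top = math.floor(bottom_row) + 1
    pad_bot = min(rows - 1, math.floor(bottom_row + pad / pitch))
    if pad_top <= rows - 1:
        hu[:, pad_top : pad_bot + 1, :] = spec.pad_hu

    # Aortic inserts at the tracheal-bifurcation (middle) slice.
    mid = n_slices // 2
    ry_mid = ap[mid] / (2.0 * pitch)
    cy_mid = bottom_row - ry_mid
    rad_px = aorta_radius / pitch
    aorta_centers = {
        "ascending": (cy_mid - 0.25 * ry_mid, iso_c - 0.12 * rx),
        "descending": (cy_mid + 0.45 * ry_mid, iso_c + 0.05 * rx),
    }
    for cr, cc_ in aorta_centers.values():
        r0, r1 = math.ceil(cr - rad_px), math.floor(cr + rad_px)
        c0, c1 = math.ceil(cc_ - rad_px), math.floor(cc_ + rad_px)
        rr = np.arange(r0, r1 + 1, dtype=np.float64)[:, None]
        cc2 = np.arange(c0, c1 + 1, dtype=np.float64)[None, :]
        inside = (rr - cr) ** 2 + (cc2 - cc_) ** 2 <= rad_px**2
        block = hu[mid, r0 : r1 + 1, c0 : c1 + 1]
        block[inside] = spec.aorta_hu

    if spec.noise_sd > 0:
        hu += rng.standard_normal(hu.shape, dtype=np.float32) * np.float32(spec.noise_sd)

    table_height = pad + ap_mean / 2.0 - true_offset
    meta = {
        "true_offset": float(true_offset),
        "group_label": patient.group_label,
        "pad_thickness_rendered": float(pad),
        "mean_ap_diameter": ap_mean,
        "body_width": patient.body_width,
        "aorta_rois": {
            name: {"slice": int(mid), "row": float(r), "col": float(c)}
            for name, (r, c) in aorta_centers.items()
        },
        "ctdivol": patient.ctdivol,
        "seed": spec.seed,
    }
    return CTVolume(
        hu=hu,
        dfov=dfov,
        slice_spacing=slice_spacing,
        table_height=float(table_height),
        meta=meta,
    )


def manual_group_spec(**overrides) -> CohortSpec:
    """Convenience: a CohortSpec calibrated to the manual-positioning group
    (n = 34, offsets −8.3 ± 11.6 mm)."""
    base = dict(
        n_patients=34,
        group_label="manual",
        direct_offset_dist=(-8.3, 11.6),
    )
    base.update(overrides)
    return CohortSpec(**base)


def calculated_group_spec(**overrides) -> CohortSpec:
    """Convenience: a CohortSpec calibrated to the calculated-table-height
    group (n = 33, offsets 0.2 ± 5.8 mm)."""
    base = dict(
        n_patients=33,
        group_label="calculated",
        direct_offset_dist=(0.2, 5.8),
    )
    base.update(overrides)
    return CohortSpec(**base)
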