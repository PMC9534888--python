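"""Image-based measurement of the patient's vertical center and isocenter offset.

The measurement chain mirrors routine off-centering QA on axial chest CT:

1. binarize each slice at an HU threshold and keep the body component;
2. per slice, take the midpoint between the highest and lowest skin rows;
3. average the midpoints along the scan length (the "grand" center);
4. convert the row offset from the isocenter to mm through the pixel pitch
   (354/512 mm per pixel at the default reconstruction), signed so that a
   patient above the isocenter has positive distance;
5. derive body thickness (averaged AP extent), body width (middle slice),
   the distance-to-thickness ratio, the >20 mm off-centering flag, and —
   when the table height is known — an estimate of the pad thickness the
   patient is actually lying on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "BodyMask",
    "CenteringResult",
    "binarize",
    "slice_center",
    "grand_center",
    "isocenter_distance",
    "body_metrics",
    "distance_ratio",
    "pad_thickness_estimate",
    "measure",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

# Separates soft tissue and skin (> -250 HU) from the foam pad and air.
DEFAULT_THRESHOLD = -250.0

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class BodyMask:
    """Per-slice body segmentation aligned to a :class:`CTVolume`."""

    mask: np.ndarray  # 3D boolean, [slice, row, column]
    threshold_hu: float
    component_policy: str = (
        "largest per-slice 8-connected component above threshold, after "
        "discarding components touching the bottom image border"
    )

    @property
    def empty_slices(self) -> np.ndarray:
        """Boolean array: True where a slice has no body component."""
        return ~self.mask.any(axis=(1, 2))


@dataclass
class CenteringResult:
    """Everything measured from one volume.

    ``isocenter_distance`` is signed in mm, positive above the isocenter.
    ``pad_thickness_estimate`` is None when the table height is unknown.
    """

    per_slice_center_row: np.ndarray  # continuous row per slice, NaN if empty
    grand_center_row: float
    isocenter_distance: float  # mm, signed (d)
    abs_distance: float  # mm, |d|
    body_thickness: float  # mm, averaged AP extent (T)
    body_width: float  # mm, middle-slice lateral extent (W)
    distance_ratio: float  # %, signed d/T*100
    distance_ratio_abs: float  # %, |d|/T*100
    offset_gt_20: bool
    pad_thickness_estimate: Optional[float]  # mm
    threshold_hu: float = DEFAULT_THRESHOLD
    pixel_pitch: float = 354.0 / 512.0
    n_empty_slices: int = 0
    component_policy: str = ""

    def to_dict(self) -> dict:
        d = {
            "grand_center_row": self.grand_center_row,
            "isocenter_distance_mm": self.isocenter_distance,
            "abs_distance_mm": self.abs_distance,
            "body_thickness_mm": self.body_thickness,
            "body_width_mm": self.body_width,
            "distance_ratio_pct": self.distance_ratio,
            "distance_ratio_abs_pct": self.distance_ratio_abs,
            "offset_gt_20": bool(self.offset_gt_20),
            "pad_thickness_estimate_mm": self.pad_thickness_estimate,
            "threshold_hu": self.threshold_hu,
            "pixel_pitch_mm": self.pixel_pitch,
            "n_empty_slices": self.n_empty_slices,
            "component_policy": self.component_policy,
            "per_slice_center_row": [
                None if math.isnan(v) else float(v) for v in self.per_slice_center_row
            ],
        }
        return d


def binarize(volume: CTVolume, threshold: float = DEFAULT_THRESHOLD) -> BodyMask:
    """Segment the body on every axial slice.

    Voxels at or above ``threshold`` HU are candidates.  Per slice,
    8-connected components touching the bottom image border (table or pad
    remnants extending out of the field of view) are discarded before the
    largest remaining component is kept as the body.  A slice with no
    component left is flagged empty and excluded from downstream averages.
    """
    hu = volume.hu
    out = np.zeros(hu.shape, dtype=bool)
    for k in range(hu.shape[0]):
        binary = hu[k] >= threshold
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=_CONN8)
        if n == 0:
            continue
        bottom_labels = np.unique(labels[-1, :])
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        sizes[bottom_labels] = 0
        if sizes.max() == 0:
            continue
        out[k] = labels == int(sizes.argmax())
    mask = BodyMask(mask=out, threshold_hu=float(threshold))
    n_empty = int(mask.empty_slices.sum())
    if n_empty:
        logger.warning("%d of %d slices have no body component", n_empty, hu.shape[0])
    return mask


def slice_center(mask_slice: np.ndarray) -> float:
    """Midpoint row between the highest and lowest occupied skin rows.

    Returns NaN for an empty slice (consumed by :func:`grand_center`).
    """
    rows = np.flatnonzero(mask_slice.any(axis=1))
    if rows.size == 0:
        return float("nan")
    return (rows[0] + rows[-1]) / 2.0


def grand_center(centers: Sequence[float]) -> float:
    """Unweighted mean of per-slice centers over non-empty slices."""
    arr = np.asarray(centers, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("all slices empty: no body found in the volume")
    return float(valid.mean())


def isocenter_distance(grand_center_row: float, volume: CTVolume) -> float:
    """Signed vertical distance (mm) from the isocenter to the grand center.

    Rows increase downward, so a center *above* the isocenter (smaller row)
    yields a positive distance: ``d = (iso_row - center_row) * pitch``.
    """
    iso_row = volume.isocenter_rc[0]
    return float((iso_row - grand_center_row) * volume.pixel_pitch)


def body_metrics(mask: BodyMask, volume: CTVolume) -> tuple[float, float]:
    """(averaged AP thickness, middle-slice lateral width), both mm.

    Extents are counted inclusively (a single-voxel body is one pitch
    thick).  Thickness averages over non-empty slices; width is read on the
    middle slice (0-based ``floor(n/2)``), falling back to the nearest
    non-empty slice if the middle one is empty.
    """
    pitch = volume.pixel_pitch
    m = mask.mask
    n_slices = m.shape[0]
    thicknesses = []
    for k in range(n_slices):
        rows = np.flatnonzero(m[k].any(axis=1))
        if rows.size:
            thicknesses.append((rows[-1] - rows[0] + 1) * pitch)
    if not thicknesses:
        raise ValueError("all slices empty: body metrics undefined")

    mid = n_slices // 2
    if not m[mid].any():
        non_empty = np.flatnonzero(m.any(axis=(1, 2)))
        mid_new = int(non_empty[np.argmin(np.abs(non_empty - mid))])
        logger.warning("middle slice %d empty; using nearest non-empty %d", mid, mid_new)
        mid = mid_new
    cols = np.flatnonzero(m[mid].any(axis=0))
    width = (cols[-1] - cols[0] + 1) * pitch
    return float(np.mean(thicknesses)), float(width)


def distance_ratio(d: float, thickness: float, absolute: bool = False) -> float:
    """Isocenter distance as a percentage of body thickness.

    Signed by default; ``absolute=True`` returns ``|d|/T*100``.
    """
    if thickness <= 0:
        raise ValueError("body thickness must be positive")
    value = d / thickness * 100.0
    return abs(value) if absolute else value


def pad_thickness_estimate(table_height: float, d: float, thickness: float) -> float:
    """Back-calculate the thickness of the pad the patient is lying on.

    Geometry: the tabletop is ``table_height`` below the isocenter, the
    lowest skin point rests on the pad top, and the body center sits
    ``thickness/2`` above that point while being ``d`` from the isocenter:

        pad = table_height + d - thickness/2

    A non-positive result triggers a warning (implausible geometry) but is
    still returned.
    """
    pad = table_height + d - thickness / 2.0
    if pad <= 0:
        warnings.warn(
            f"pad thickness estimate {pad:.1f} mm is non-positive; check the "
            "table height and segmentation",
            stacklevel=2,
        )
    return pad


def measure(volume: CTVolume, threshold: float = DEFAULT_THRESHOLD) -> CenteringResult:
    """Run the full centering measurement on one volume."""
    mask = binarize(volume, threshold)
    centers = np.array([slice_center(mask.mask[k]) for k in range(volume.n_slices)])
    grand = grand_center(centers)
    d = isocenter_distance(grand, volume)
    thickness, width = body_metrics(mask, volume)
    pad = (
        pad_thickness_estimate(volume.table_height, d, thickness)
        if volume.table_height is not None
        else None
    )
    if pad is None:
        logger.warning("table height unknown: pad thickness estimate unavailable")
    return CenteringResult(
        per_slice_center_row=centers,
        grand_center_row=grand,
        isocenter_distance=d,
        abs_distance=abs(d),
        body_thickness=thickness,
        body_width=width,
        distance_ratio=distance_ratio(d, thickness),
        distance_ratio_abs=distance_ratio(d, thickness, absolute=True),
        offset_gt_20=abs(d) > 20.0,
        pad_thickness_estimate=pad,
        threshold_hu=float(threshold),
        pixel_pitch=volume.pixel_pitch,
        n_empty_slices=int(mask.empty_slices.sum()),
        component_policy=mask.component_policy,
    )
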