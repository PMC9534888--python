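"""ROI-based image quality: SNR and dose-normalized SNR (SNRD).

SNR is the ratio of the mean HU to the HU standard deviation inside a
circular region of interest, conventionally drawn in the ascending and
descending aorta at the level of the tracheal bifurcation on
contrast-enhanced scans.  SNRD divides SNR by the square root of a dose
metric to remove the trivial noise-dose dependence (quantum noise scales
as dose^(-1/2)), so differences in SNRD reflect positioning and filtration
effects rather than tube output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import CTVolume

__all__ = ["RoiSpec", "QualityReport", "roi_stats", "snr", "snrd", "quality_report"]

DEFAULT_ROI_RADIUS = 2.5  # mm


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI on one axial slice.

    ``center_rc`` is a continuous (row, col) image coordinate; ``radius`` is
    in mm and converted through the volume's pixel pitch.
    """

    center_rc: tuple[float, float]
    radius: float = DEFAULT_ROI_RADIUS
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass(frozen=True)
class QualityReport:
    roi_name: str
    roi_mean: float  # HU
    roi_sd: float  # HU
    snr: float
    dose_for_normalization: float  # mGy
    dose_metric: str  # "ctdivol" or "ssde"
    snrd: float

    def to_dict(self) -> dict:
        return {
            "roi": self.roi_name,
            "roi_mean_hu": self.roi_mean,
            "roi_sd_hu": self.roi_sd,
            "snr": self.snr,
            "dose_for_normalization_mGy": self.dose_for_normalization,
            "dose_metric": self.dose_metric,
            "snrd": self.snrd,
        }


def roi_stats(volume: CTVolume, roi: RoiSpec) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) of HU over voxels whose centers lie
    inside the ROI circle.

    Raises if the circle extends outside the image or covers fewer than
    two voxel centers.
    """
    if not 0 <= roi.slice_index < volume.n_slices:
        raise ValueError(f"slice index {roi.slice_index} outside volume")
    pitch = volume.pixel_pitch
    cr, cc = roi.center_rc
    rad_px = roi.radius / pitch
    _, rows, cols = volume.shape
    if cr - rad_px < 0 or cr + rad_px > rows - 1 or cc - rad_px < 0 or cc + rad_px > cols - 1:
        raise ValueError("ROI extends outside the image")
    r0, r1 = math.ceil(cr - rad_px), math.floor(cr + rad_px)
    c0, c1 = math.ceil(cc - rad_px), math.floor(cc + rad_px)
    rr = np.arange(r0, r1 + 1, dtype=float)[:, None]
    cc2 = np.arange(c0, c1 + 1, dtype=float)[None, :]
    inside = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= rad_px**2
    values = volume.hu[roi.slice_index, r0 : r1 + 1, c0 : c1 + 1][inside]
    if values.size < 2:
        raise ValueError(f"ROI covers {values.size} voxel(s); need at least 2")
    return float(values.mean()), float(values.std(ddof=1))


def snr(mean: float, sd: float) -> float:
    """Signal-to-noise ratio mean/sd; undefined for sd = 0."""
    if sd <= 0:
        raise ValueError("SNR undefined for non-positive SD")
    return mean / sd


def snrd(snr_value: float, dose: float) -> float:
    """Dose-normalized SNR: snr / sqrt(dose)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return snr_value / math.sqrt(dose)


def quality_report(
    volume: CTVolume,
    roi: RoiSpec,
    dose: float,
    roi_name: str = "roi",
    dose_metric: str = "ctdivol",
) -> QualityReport:
    """ROI statistics, SNR and SNRD in one record."""
    mean, sd = roi_stats(volume, roi)
    s = snr(mean, sd)
    return QualityReport(
        roi_name=roi_name,
        roi_mean=mean,
        roi_sd=sd,
        snr=s,
        dose_for_normalization=dose,
        dose_metric=dose_metric,
        snrd=snrd(s, dose),
    )
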