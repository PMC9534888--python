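"""Size-specific dose estimates (SSDE), effective diameter, and DLP.

SSDE rescales the scanner-reported CTDIvol — which is referenced to a 16 cm
or 32 cm acrylic phantom — to the actual patient size.  The size metric is
the geometric effective diameter, sqrt(AP thickness x lateral width).  The
conversion factor follows the standard exponential fit to the AAPM consensus
coefficients:

    f(D) = a * exp(-b * D),   SSDE = f(D) * CTDIvol

with (a, b) depending on the reference phantom.  For pediatric diameters the
factor exceeds 1: small patients absorb more dose than the reference phantom
at the same CTDIvol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DoseReport",
    "effective_diameter",
    "conversion_factor",
    "ssde",
    "dlp",
    "dose_report",
    "SSDE_COEFFICIENTS",
    "DIAMETER_RANGE_CM",
]

# Exponential-fit coefficients (a, b) per reference phantom diameter (cm),
# valid for effective diameters of 6-55 cm.
SSDE_COEFFICIENTS: dict[int, tuple[float, float]] = {
    32: (3.704369, 0.03671937),
    16: (1.874799, 0.03871313),
}
DIAMETER_RANGE_CM = (6.0, 55.0)


@dataclass(frozen=True)
class DoseReport:
    """Per-patient dose summary."""

    ctdivol: float  # mGy, referenced to `phantom_cm`
    phantom_cm: int  # 16 or 32
    scan_length: float  # mm
    dlp: float  # mGy*cm
    effective_diameter: float  # cm
    conversion_factor: float  # dimensionless
    ssde: float  # mGy

    def to_dict(self) -> dict:
        return {
            "ctdivol_mGy": self.ctdivol,
            "reference_phantom_cm": self.phantom_cm,
            "scan_length_mm": self.scan_length,
            "dlp_mGy_cm": self.dlp,
            "effective_diameter_cm": self.effective_diameter,
            "conversion_factor": self.conversion_factor,
            "ssde_mGy": self.ssde,
        }


def effective_diameter(thickness_mm: float, width_mm: float) -> float:
    """Geometric effective diameter in cm: sqrt(T_cm * W_cm)."""
    if thickness_mm <= 0 or width_mm <= 0:
        raise ValueError("thickness and width must be positive")
    return math.sqrt((thickness_mm / 10.0) * (width_mm / 10.0))


def conversion_factor(eff_diam_cm: float, phantom: int = 32) -> float:
    """Size-dependent CTDIvol-to-SSDE factor f(D) = a*exp(-b*D)."""
    try:
        a, b = SSDE_COEFFICIENTS[phantom]
    except KeyError:
        raise ValueError(
            f"reference phantom must be one of {sorted(SSDE_COEFFICIENTS)}, got {phantom}"
        ) from None
    lo, hi = DIAMETER_RANGE_CM
    if not lo <= eff_diam_cm <= hi:
        raise ValueError(
            f"effective diameter {eff_diam_cm:.1f} cm outside the valid "
            f"range [{lo:.0f}, {hi:.0f}] cm"
        )
    return a * math.exp(-b * eff_diam_cm)


def ssde(ctdivol: float, eff_diam_cm: float, phantom: int = 32) -> float:
    """Size-specific dose estimate in mGy."""
    if ctdivol < 0:
        raise ValueError("ctdivol must be non-negative")
    return conversion_factor(eff_diam_cm, phantom) * ctdivol


def dlp(ctdivol: float, scan_length_mm: float) -> float:
    """Dose-length product in mGy*cm."""
    if scan_length_mm < 0:
        raise ValueError("scan length must be non-negative")
    return ctdivol * scan_length_mm / 10.0


def dose_report(
    ctdivol: float,
    thickness_mm: float,
    width_mm: float,
    scan_length_mm: float,
    phantom: int = 32,
) -> DoseReport:
    """Assemble the full dose summary for one patient."""
    d = effective_diameter(thickness_mm, width_mm)
    f = conversion_factor(d, phantom)
    return DoseReport(
        ctdivol=ctdivol,
        phantom_cm=phantom,
        scan_length=scan_length_mm,
        dlp=dlp(ctdivol, scan_length_mm),
        effective_diameter=d,
        conversion_factor=f,
        ssde=f * ctdivol,
    )
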