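"""Table-height planning from a pre-scan chest-thickness measurement.

The scanner's table height is the distance (mm) from the gantry isocenter
down to the tabletop.  With a pad system of nominal thickness ``pad`` (mm)
on the table and the patient supine on top, the patient's vertical center
sits ``pad + chest/2`` above the tabletop, so setting

    table height = pad + chest thickness / 2

places the patient's center at the isocenter.  The tabletop on the scanner
modeled here can rise only to 100 mm below the isocenter, so a required
height below that limit is infeasible for thin patients on a thin pad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "PositioningPlan",
    "set_table_height",
    "predicted_offset",
    "make_plan",
    "MIN_TABLE_HEIGHT",
    "DEFAULT_PAD",
]

DEFAULT_PAD = 75.0  # mm, nominal pad-system thickness
MIN_TABLE_HEIGHT = 100.0  # mm, hardware limit below the isocenter


@dataclass(frozen=True)
class PositioningPlan:
    """The planned table height for one patient and its feasibility."""

    measured_chest_thickness: float  # mm
    pad_constant: float  # mm
    set_table_height: float  # mm below isocenter
    feasible: bool  # True when the height respects the hardware limit

    @property
    def max_table_height(self) -> float:
        return MIN_TABLE_HEIGHT


def set_table_height(chest: float, pad: float = DEFAULT_PAD) -> float:
    """Ideal table height (mm) for a measured chest thickness.

    Returns ``pad + chest/2``.  Emits a warning (not an error) when the
    result is below the 100 mm hardware limit — the table cannot physically
    reach that position, but scanner behavior at the limit is not modeled.
    """
    if chest < 0:
        raise ValueError(f"chest thickness must be >= 0, got {chest}")
    height = pad + chest / 2.0
    if height < MIN_TABLE_HEIGHT:
        warnings.warn(
            f"required table height {height:.1f} mm is above the hardware "
            f"limit ({MIN_TABLE_HEIGHT:.0f} mm below isocenter); the table "
            "cannot reach this position",
            stacklevel=2,
        )
    return height


def predicted_offset(true_chest: float, pad_actual: float, set_height: float) -> float:
    """Signed vertical offset (mm, up = positive) of the patient center
    from the isocenter, given the actual pad thickness under load and the
    table height actually set.

    ``pad_actual + true_chest/2`` is the center's height above the tabletop;
    the tabletop is ``set_height`` below the isocenter.  Setting the height
    from a perfect measurement on an undented pad returns exactly zero.
    """
    if true_chest <= 0 or pad_actual <= 0 or set_height <= 0:
        raise ValueError("true_chest, pad_actual and set_height must be positive")
    return pad_actual + true_chest / 2.0 - set_height


def make_plan(chest: float, pad: float = DEFAULT_PAD) -> PositioningPlan:
    """Build a :class:`PositioningPlan`, flagging hardware infeasibility."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        height = set_table_height(chest, pad)
    return PositioningPlan(
        measured_chest_thickness=chest,
        pad_constant=pad,
        set_table_height=height,
        feasible=height >= MIN_TABLE_HEIGHT,
    )
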