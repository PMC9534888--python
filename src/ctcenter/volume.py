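"""In-memory CT volume container.

Axis convention (documented in every serialized output): the HU array is
indexed ``[slice, row, column]``; the row index increases *downward* in the
patient's anterior–posterior direction, so a structure above the gantry
isocenter has a smaller row index than the isocenter row.  Voxel centers sit
at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A reconstructed axial CT volume in Hounsfield units.

    Parameters
    ----------
    hu : ndarray, shape (n_slices, rows, columns)
        Voxel values in HU (air ≈ -1000).
    dfov : float
        Display field of view in mm.  The pixel pitch is ``dfov / columns``;
        with the default 354 mm DFOV on a 512 matrix the pitch is
        354/512 ≈ 0.6914 mm.
    slice_spacing : float
        Spacing between consecutive axial slices, mm.
    table_height : float, optional
        Scanner table height: distance in mm from the gantry isocenter down
        to the tabletop surface.  ``None`` when unknown (pad-thickness
        estimation is then unavailable).
    isocenter_rc : (float, float), optional
        Continuous (row, column) coordinate of the gantry isocenter in image
        space.  Defaults to the image center ``((rows-1)/2, (cols-1)/2)``,
        matching reconstructions whose image center coincides with the
        isocenter.
    meta : dict
        Free-form provenance (ground truth for phantoms, rescale
        description for real data, ...).
    """

    hu: np.ndarray
    dfov: float = 354.0
    slice_spacing: float = 5.0
    table_height: Optional[float] = None
    isocenter_rc: Optional[tuple[float, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError(
                f"hu must be a 3D [slice, row, column] array, got ndim={self.hu.ndim}"
            )
        if self.dfov <= 0:
            raise ValueError("dfov must be positive")
        if self.isocenter_rc is None:
            n_slices, rows, cols = self.hu.shape
            self.isocenter_rc = ((rows - 1) / 2.0, (cols - 1) / 2.0)

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def pixel_pitch(self) -> float:
        """In-plane pixel size in mm (dfov / columns)."""
        return self.dfov / self.hu.shape[2]
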