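"""In-memory CT volume container.

Voxels are stored as a 3-D array of Hounsfield units indexed ``[ix, iy, iz]``
with axis semantics (image-horizontal, image-vertical, longitudinal/couch
readout).  ``origin`` is the lab position of the centre of voxel (0, 0, 0);
the longitudinal coordinate of slice ``k`` is ``origin[2] + k * spacing[2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Lab coordinates (mm) of voxel centres along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    @property
    def x_coords(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y_coords(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(2)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to lab mm."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map lab mm (..., 3) to fractional voxel indices."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)
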