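"""Voxel grid geometry shared by the optical and acoustic stages.

The simulation domain is a cube of 140 voxels per axis with 0.1 mm edges
(14 mm per side).  Voxel ``(i, j, k)`` occupies the half-open cell
``[i*dx, (i+1)*dx) x ... `` so its center sits at ``(i + 0.5) * dx``.
Physical coordinates are in millimetres throughout the optical stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular voxel grid with cubic voxels.

    Parameters
    ----------
    shape
        Voxel counts along (x, y, z).
    spacing
        Voxel edge length in mm.
    """

    shape: tuple[int, int, int] = (140, 140, 140)
    spacing: float = 0.1

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size per axis in mm."""
        return tuple(n * self.spacing for n in self.shape)

    def index_of(self, coord: float, axis: int) -> int:
        """Map a physical coordinate (mm) to a voxel index.

        Uses ``floor(p / spacing)`` clamped to the grid, so a nominal
        position of 7 mm lands on index 70 (voxel center 7.05 mm).
        """
        i = int(np.floor(coord / self.spacing))
        return min(max(i, 0), self.shape[axis] - 1)

    def indices_of(self, point: tuple[float, float, float]) -> tuple[int, int, int]:
        return tuple(self.index_of(p, a) for a, p in enumerate(point))

    def center_of(self, index: tuple[int, ...]) -> tuple[float, ...]:
        """Physical coordinates (mm) of a voxel center."""
        return tuple((i + 0.5) * self.spacing for i in index)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        return (np.arange(self.shape[axis]) + 0.5) * self.spacing

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return self.spacing**3


DEFAULT_GEOMETRY = GridGeometry()
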