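"""Volumetric dose grids and structure masks.

A :class:`DoseGrid` is a regular, axis-aligned 3D scalar field of absorbed
dose in cGy. A :class:`StructureMask` is a boolean field congruent with a
grid; congruence (same shape, same spacing) is a hard requirement — no
resampling is performed anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "StructureMask"]


@dataclass
class DoseGrid:
    """Regular 3D dose field.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Absorbed dose per voxel in cGy. Must be non-negative.
    spacing : sequence of 3 floats
        Voxel edge lengths along each axis, in mm. Strictly positive.
    origin : sequence of 3 floats, optional
        Physical position of the centre of voxel (0, 0, 0), in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"dose array must be 3D, got ndim={self.values.ndim}")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm³ (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class StructureMask:
    """Named boolean voxel mask congruent with a :class:`DoseGrid`."""

    name: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask array must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cc(self) -> float:
        return int(self.voxels.sum()) * self.voxel_volume_cc

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def check_congruent(self, grid: DoseGrid) -> None:
        """Raise if this mask cannot index ``grid``."""
        if self.voxels.shape != grid.values.shape:
            raise ValueError(
                f"mask {self.name!r} shape {self.voxels.shape} does not match "
                f"grid shape {grid.values.shape}"
            )
        if not np.allclose(self.spacing, grid.spacing):
            raise ValueError(
                f"mask {self.name!r} spacing {self.spacing} does not match "
                f"grid spacing {grid.spacing}"
            )
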