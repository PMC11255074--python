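"""Voxel-grid bookkeeping and the in-memory volume/mask containers.

All volumes in an analysis must live on one shared grid: the package never
resamples, it *rejects* mismatches. The NIfTI affine is carried opaquely so
volumes round-trip through disk unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DimensionalityError,
    EmptyMaskError,
    GridMismatchError,
    NegativeDataError,
    NonFiniteDataError,
)


@dataclass(frozen=True)
class VoxelGrid:
    """Shape, physical voxel size (mm) and affine of a 3D sampling grid."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: 4x4 voxel-to-world affine, carried for NIfTI round-trips only.
    affine: tuple = field(default=None, compare=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3:
            raise DimensionalityError(f"grid must be 3D, got shape {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"all grid dimensions must be >= 1, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        aff = self.affine
        if aff is None:
            aff = np.diag(list(vs) + [1.0])
        object.__setattr__(
            self, "affine", tuple(map(tuple, np.asarray(aff, dtype=float)))
        )

    @property
    def affine_matrix(self) -> np.ndarray:
        return np.asarray(self.affine, dtype=float)

    def compatible_with(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )


def require_same_grid(a, b, what="volumes"):
    """Raise :class:`GridMismatchError` unless two gridded objects agree."""
    if not a.grid.compatible_with(b.grid):
        raise GridMismatchError(
            f"{what} on different grids: {a.grid.shape}/{a.grid.voxel_size}"
            f" vs {b.grid.shape}/{b.grid.voxel_size}"
        )


@dataclass
class GMVolume:
    """A modulated gray-matter volume (arbitrary units, >= 0) on a grid."""

    grid: VoxelGrid
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise DimensionalityError(
                f"volume data must be 3D, got {values.ndim}D"
            )
        if tuple(values.shape) != self.grid.shape:
            raise GridMismatchError(
                f"data shape {values.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(values).all():
            raise NonFiniteDataError(
                f"volume '{self.subject_id}' contains NaN or Inf voxels"
            )
        if (values < 0).any():
            raise NegativeDataError(
                f"volume '{self.subject_id}' contains negative gray-matter values"
            )
        self.values = values


@dataclass
class BrainMask:
    """Boolean inclusion mask defining the support of spatial statistics."""

    grid: VoxelGrid
    include: np.ndarray

    def __post_init__(self):
        inc = np.asarray(self.include, dtype=bool)
        if inc.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {inc.ndim}D")
        if tuple(inc.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {inc.shape} does not match grid {self.grid.shape}"
            )
        if not inc.any():
            raise EmptyMaskError("mask selects no voxels")
        self.include = inc

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())
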