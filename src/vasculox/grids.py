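"""Voxel-grid containers shared across the package.

All grids are isotropic 3D scalar fields. Physical coordinates are in
micrometres; a point ``p`` maps to the voxel whose centre is nearest,
``round((p - origin) / spacing)`` with 0-based indices. The in-memory
arrays are plain numpy; the column-major (first index fastest) element
order only matters on disk and is handled by the raw-volume reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "VesselGrid", "OxygenField"]


@dataclass
class VoxelGrid:
    """A 3D scalar field with isotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        One scalar per voxel.
    spacing : float
        Isotropic voxel edge, micrometres.
    origin : ndarray, shape (3,)
        Physical position (micrometres) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: float = 10.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def point_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map physical point(s) (μm) to nearest-voxel indices (may be out of range)."""
        p = np.asarray(point, dtype=float)
        return np.rint((p - self.origin) / self.spacing).astype(int)

    def index_to_point(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class VesselGrid:
    """Binary vessel mask plus per-vessel-voxel path distance from the tree root.

    ``path_distance`` holds the centreline arc length (μm) from the root for
    vessel voxels and ``+inf`` elsewhere; where several segments deposit the
    same voxel the minimum is kept.
    """

    mask: np.ndarray
    path_distance: np.ndarray
    spacing: float = 10.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.path_distance = np.asarray(self.path_distance, dtype=float)
        if self.mask.shape != self.path_distance.shape:
            raise ValueError("mask and path_distance shapes differ")
        self.origin = np.asarray(self.origin, dtype=float)
        d = self.path_distance[self.mask]
        if d.size and (not np.all(np.isfinite(d)) or np.any(d < 0)):
            raise ValueError("path distance must be finite and non-negative on vessel voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_vessel_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class OxygenField:
    """A pO₂ field (mmHg) with its vessel mask and fixed intravascular sources.

    On vessel voxels the field equals ``source``; the solver re-imposes these
    Dirichlet values after every diffusion step.
    """

    values: np.ndarray
    mask: np.ndarray
    source: np.ndarray
    spacing: float = 10.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.source = np.asarray(self.source, dtype=float)
        if not (self.values.shape == self.mask.shape == self.source.shape):
            raise ValueError("values, mask and source shapes differ")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def point_to_index(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return np.rint((p - self.origin) / self.spacing).astype(int)

    def copy(self) -> "OxygenField":
        return OxygenField(self.values.copy(), self.mask, self.source,
                           self.spacing, self.origin.copy())

    def crop(self, lo: int, hi: int | None = None) -> "OxygenField":
        """Remove ``lo`` voxels from each low face and ``hi`` from each high face."""
        hi = lo if hi is None else hi
        sl = tuple(slice(lo, n - hi) for n in self.shape)
        return OxygenField(self.values[sl], self.mask[sl], self.source[sl],
                           self.spacing, self.origin + lo * self.spacing)
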