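"""Raw-volume I/O in the deposited-data dialect.

Volumes are headerless single-precision little-endian blobs in
column-major order (first index fastest), one float per voxel; the
geometry lives in a JSON sidecar (shape, spacing, origin, plus free-form
provenance entries such as iteration counts or a parameter hash).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import VoxelGrid

__all__ = ["RawVolumeSpec", "read_raw_volume", "write_raw_volume",
           "read_sidecar", "write_sidecar"]

_DTYPE = np.dtype("<f4")


@dataclass(frozen=True)
class RawVolumeSpec:
    """Location and layout of a raw volume on disk."""

    path: str | Path
    shape: tuple[int, int, int]
    spacing: float = 10.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    order: str = "F"   # column-major; "C" flips for foreign data

    @property
    def n_bytes(self) -> int:
        return int(np.prod(self.shape)) * _DTYPE.itemsize


def read_raw_volume(spec: RawVolumeSpec) -> VoxelGrid:
    """Read a raw volume, checking the file size against the declared shape."""
    path = Path(spec.path)
    actual = path.stat().st_size
    if actual != spec.n_bytes:
        raise ValueError(
            f"{path}: expected {spec.n_bytes} bytes for shape {spec.shape}, "
            f"found {actual}")
    flat = np.fromfile(path, dtype=_DTYPE)
    values = flat.reshape(spec.shape, order=spec.order).astype(float)
    n_bad = int(np.count_nonzero(~np.isfinite(values)))
    if n_bad:
        warnings.warn(f"{path}: {n_bad} non-finite voxels", stacklevel=2)
    return VoxelGrid(values, spacing=spec.spacing, origin=np.asarray(spec.origin))


def write_raw_volume(grid, spec: RawVolumeSpec) -> Path:
    """Write a volume in the raw dialect; inverse of :func:`read_raw_volume`.

    The dtype is forced to little-endian float32 regardless of platform.
    Values outside the float32 range raise rather than silently overflow.
    """
    values = np.asarray(getattr(grid, "values", grid))
    if tuple(values.shape) != tuple(spec.shape):
        raise ValueError(f"grid shape {values.shape} != spec shape {spec.shape}")
    finite = values[np.isfinite(values)]
    if finite.size and np.max(np.abs(finite)) > np.finfo(np.float32).max:
        raise OverflowError("values exceed the float32 range")
    path = Path(spec.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values.astype(_DTYPE).ravel(order=spec.order).tofile(path)
    return path


def write_sidecar(spec: RawVolumeSpec, extra: dict | None = None) -> Path:
    meta = {
        "shape": list(spec.shape),
        "spacing_um": spec.spacing,
        "origin_um": list(spec.origin),
        "dtype": "float32",
        "endianness": "little",
        "element_order": "column-major" if spec.order == "F" else "row-major",
    }
    if extra:
        meta.update(extra)
    path = Path(str(spec.path) + ".json")
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_sidecar(volume_path: str | Path) -> RawVolumeSpec:
    with open(str(volume_path) + ".json") as fh:
        meta = json.load(fh)
    return RawVolumeSpec(
        path=volume_path,
        shape=tuple(meta["shape"]),
        spacing=float(meta.get("spacing_um", 10.0)),
        origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        order="F" if meta.get("element_order", "column-major") == "column-major" else "C",
    )
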