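"""Voxelization of vessel trees.

Segment centrelines are discretised with a 3D Bresenham line walk (no
gaps, 26-connected, one voxel per driving-axis step), then dilated by a
spherical kernel matching each segment's radius; the union of the dilated
segments, thresholded to binary, is the vessel mask. Alongside the mask a
path-distance field records, per vessel voxel, the centreline arc length
from the tree root of the segment that deposited it (minimum over
depositing segments) — downstream this drives the linear intravascular
oxygen assignment.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import VesselGrid
from .trees import VesselTree

__all__ = ["bresenham_3d", "spherical_kernel", "ball_offsets", "rasterize_tree"]


def bresenham_3d(a, b) -> np.ndarray:
    """Integer line walk from voxel ``a`` to voxel ``b``, inclusive.

    Returns an (n, 3) index array with n = max(|Δx|, |Δy|, |Δz|) + 1.
    Consecutive voxels differ by at most one step per coordinate, so the
    path is 26-connected with no gaps. The driving axis is the dominant
    one, ties broken x > y > z; reversing the endpoints may differ by
    sub-voxel rounding choices.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    delta = b - a
    n = int(np.max(np.abs(delta)))
    if n == 0:
        return a.reshape(1, 3)
    # dominant axis drives; remaining two accumulate error terms
    drive = int(np.argmax(np.abs(delta)))   # argmax → first max → x > y > z
    others = [ax for ax in range(3) if ax != drive]
    step = np.sign(delta)
    ad = np.abs(delta)
    out = np.empty((n + 1, 3), dtype=int)
    out[0] = a
    p = a.copy()
    err = [2 * ad[ax] - ad[drive] for ax in others]
    for i in range(n):
        p[drive] += step[drive]
        for j, ax in enumerate(others):
            if err[j] > 0:
                p[ax] += step[ax]
                err[j] -= 2 * ad[drive]
            err[j] += 2 * ad[ax]
        out[i + 1] = p
    return out


def spherical_kernel(radius_um: float, spacing_um: float) -> np.ndarray:
    """Boolean ball kernel: True where the voxel centre lies within the radius.

    Boundary voxels whose centre is exactly on the sphere are included.
    A radius below half a voxel yields a degenerate 1×1×1 kernel (warned):
    the vessel is thinner than the grid can represent.
    """
    if radius_um < spacing_um / 2.0:
        warnings.warn(
            f"radius {radius_um} μm below half the voxel size "
            f"{spacing_um} μm; using a single-voxel kernel", stacklevel=2)
        return np.ones((1, 1, 1), dtype=bool)
    half = int(np.floor(radius_um / spacing_um))
    ax = np.arange(-half, half + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    dist2 = (dx * dx + dy * dy + dz * dz) * spacing_um ** 2
    return dist2 <= radius_um ** 2 + 1e-9


def ball_offsets(radius_um: float, spacing_um: float) -> np.ndarray:
    """(k, 3) integer offsets of the voxels inside the spherical kernel."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kern = spherical_kernel(radius_um, spacing_um)
    half = kern.shape[0] // 2
    return np.argwhere(kern) - half


def rasterize_tree(tree: VesselTree,
                   spacing: float = 10.0,
                   pad_um: float = 0.0,
                   origin: np.ndarray | None = None,
                   shape: tuple[int, int, int] | None = None,
                   clip: bool = False,
                   max_voxels: int = 1_500_000_000) -> VesselGrid:
    """Voxelize a tree into a binary mask with per-voxel root path distance.

    By default the grid is sized to the tree's bounding box (inflated by the
    largest radius) plus ``pad_um`` per side; pass ``origin``/``shape`` to
    rasterize into a prescribed frame instead (with ``clip=True`` voxels
    falling outside it are dropped silently — used when pasting a tree into
    a shared sample grid).
    """
    if origin is None or shape is None:
        lo, hi = tree.bounding_box(margin_um=pad_um)
        origin = lo
        shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    origin = np.asarray(origin, dtype=float)
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"requested grid {shape} exceeds the addressable size; "
            "partition the tree or coarsen the spacing")

    mask = np.zeros(shape, dtype=bool)
    dist = np.full(shape, np.inf)

    def to_idx(p):
        return np.rint((p - origin) / spacing).astype(int)

    arc = tree.arc_lengths()
    segs = tree.segments()
    if segs.shape[0] == 0:
        idx = to_idx(tree.positions[tree.root_index])
        if np.all(idx >= 0) and np.all(idx < np.asarray(shape)):
            mask[tuple(idx)] = True
            dist[tuple(idx)] = 0.0
        elif not clip:
            raise ValueError("tree root falls outside the prescribed grid")
        return VesselGrid(mask, dist, spacing, origin)

    shape_arr = np.asarray(shape)
    for pa, ch in segs:
        line = bresenham_3d(to_idx(tree.positions[pa]), to_idx(tree.positions[ch]))
        m = line.shape[0]
        seg_len = np.linalg.norm(tree.positions[ch] - tree.positions[pa])
        if m > 1:
            line_dist = arc[pa] + seg_len * np.arange(m) / (m - 1)
        else:
            line_dist = np.array([arc[pa]])
        offs = ball_offsets(tree.radii[ch], spacing)
        vox = (line[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        vdist = np.repeat(line_dist, offs.shape[0])
        inside = np.all((vox >= 0) & (vox < shape_arr), axis=1)
        if not clip and not np.all(inside):
            need = tuple(int(x) for x in vox.max(axis=0) + 1)
            raise ValueError(
                f"tree exceeds the grid; a shape of at least {need} is required")
        vox = vox[inside]
        vdist = vdist[inside]
        flat = np.ravel_multi_index(vox.T, shape)
        mask.ravel()[flat] = True
        np.minimum.at(dist.ravel(), flat, vdist)
    return VesselGrid(mask, dist, spacing, origin)
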