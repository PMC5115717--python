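"""Whole-tumour oxygen computation schemes: CTM and ITM.

The Combined Tree Method (CTM) rasterizes every microtree reaching a
cubic sample into one high-resolution grid (10 μm), solves the joint
steady state with a padded boundary that is cropped afterwards, and so
captures the competition for oxygen between adjacent trees. The
Individual Tree Method (ITM) solves each archetype once in isolation,
block-mean down-samples the result to a coarse grid (100 μm), translates
a copy to every attachment point and resolves overlaps by voxelwise
maximum — cheap enough for a whole tumour but blind to inter-tree
interaction, which biases it towards less hypoxia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import OxygenField, VesselGrid
from .oxygen import (PhysParams, SteadyStateResult, assign_vessel_po2,
                     diffusion_kernel, solve_steady_state)
from .raster import rasterize_tree
from .trees import VesselTree
from .tumour import SampleSpec, TumourModel

__all__ = [
    "ctm_field",
    "ArchetypeField",
    "precompute_archetype_fields",
    "downsample_block_mean",
    "itm_field",
    "solve_single_tree",
]


def solve_single_tree(tree: VesselTree, phys: PhysParams,
                      spacing: float = 10.0, pad_um: float = 200.0,
                      tolerance: float = 1e-4,
                      max_iter: int = 5000) -> SteadyStateResult:
    """Rasterize one tree (zero-padded frame) and solve its steady state."""
    vg = rasterize_tree(tree, spacing=spacing, pad_um=pad_um)
    field = assign_vessel_po2(vg, phys)
    return solve_steady_state(field, phys, tolerance=tolerance, max_iter=max_iter)


def ctm_field(spec: SampleSpec, phys: PhysParams,
              spacing: float = 10.0,
              tolerance: float = 1e-4, max_iter: int = 5000,
              max_voxels: int = 60_000_000,
              return_vessels: bool = False):
    """Combined Tree Method: joint steady-state solve of a padded sample.

    All trees in the spec are rasterized into one grid; where vessel voxels
    of different trees collide, both the fixed source and the mask take the
    maximum contributor. After solving, the pad (extra tumour voxels that
    only guard against boundary leakage) is cropped. Returns the cropped
    OxygenField (plus, optionally, the cropped VesselGrid).
    """
    pad_vox = int(round(spec.pad_um / spacing))
    kernel = diffusion_kernel(phys, spacing)
    min_pad = 4.0 * kernel.sigma_um
    if spec.pad_um < min_pad:
        raise ValueError(f"pad {spec.pad_um} μm below 4σ = {min_pad:.0f} μm "
                         "of one diffusion step")
    n_side = int(round(spec.side_um / spacing)) + 2 * pad_vox
    shape = (n_side, n_side, n_side)
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"sample grid {shape} too large; partition the sample into "
            f"sub-boxes of at most {int(max_voxels ** (1 / 3))}³ voxels")
    origin = spec.centre_um - spec.side_um / 2.0 - pad_vox * spacing

    mask = np.zeros(shape, dtype=bool)
    source = np.zeros(shape)
    dist = np.full(shape, np.inf)
    for tree in spec.trees():
        vg = rasterize_tree(tree, spacing=spacing, origin=origin,
                            shape=shape, clip=True)
        tree_field = assign_vessel_po2(vg, phys)
        np.maximum(source, tree_field.source, out=source)
        mask |= vg.mask
        np.minimum(dist, vg.path_distance, out=dist)

    field = OxygenField(values=source.copy(), mask=mask, source=source,
                        spacing=spacing, origin=origin)
    result = solve_steady_state(field, phys, tolerance=tolerance,
                                max_iter=max_iter, kernel=kernel)
    cropped = result.field.crop(pad_vox) if pad_vox else result.field
    if return_vessels:
        sl = tuple(slice(pad_vox, n - pad_vox) for n in shape)
        vg_c = VesselGrid(mask[sl], dist[sl], spacing,
                          origin + pad_vox * spacing)
        return cropped, vg_c, result
    return cropped


@dataclass
class ArchetypeField:
    """Precomputed steady-state field of one archetype, stored with the
    origin of its grid relative to the tree root (the attachment point)."""

    field: OxygenField
    origin_offset_um: np.ndarray   # field.origin relative to the tree root
    n_iterations: int
    converged: bool


def precompute_archetype_fields(micro_library: list[VesselTree],
                                phys: PhysParams,
                                spacing: float = 10.0,
                                pad_um: float = 200.0,
                                tolerance: float = 1e-4,
                                max_iter: int = 5000) -> list[ArchetypeField]:
    """Solve every archetype in isolation at high resolution (zero-padded
    frame, pad retained: the stored field includes the oxygenated halo)."""
    out = []
    for tree in micro_library:
        res = solve_single_tree(tree, phys, spacing=spacing, pad_um=pad_um,
                                tolerance=tolerance, max_iter=max_iter)
        root = tree.positions[tree.root_index]
        out.append(ArchetypeField(
            field=res.field,
            origin_offset_um=res.field.origin - root,
            n_iterations=res.n_iterations,
            converged=res.converged,
        ))
    return out


def downsample_block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean down-sampling: each output voxel is the mean of its
    factor³ input block. Shapes not divisible by the factor are cropped to
    the largest divisible sub-grid (trailing voxels dropped)."""
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.asarray(values).copy()
    v = np.asarray(values)
    ns = [s // factor for s in v.shape]
    if min(ns) == 0:
        raise ValueError(f"shape {v.shape} too small for factor {factor}")
    v = v[: ns[0] * factor, : ns[1] * factor, : ns[2] * factor]
    return v.reshape(ns[0], factor, ns[1], factor, ns[2], factor).mean(axis=(1, 3, 5))


def coarse_archetype_fields(fields: list[ArchetypeField],
                            coarse_spacing: float = 100.0) -> list[ArchetypeField]:
    """Down-sample precomputed archetype fields to the coarse ITM grid."""
    out = []
    for af in fields:
        factor = int(round(coarse_spacing / af.field.spacing))
        if abs(factor * af.field.spacing - coarse_spacing) > 1e-9:
            raise ValueError("coarse spacing must be an integer multiple of "
                             "the fine spacing")
        vals = downsample_block_mean(af.field.values, factor)
        # the coarse voxel centre of block (0,0,0) sits half a block in
        shift = (factor - 1) / 2.0 * af.field.spacing
        coarse = OxygenField(
            values=vals,
            mask=np.zeros(vals.shape, dtype=bool),
            source=np.zeros(vals.shape),
            spacing=coarse_spacing,
            origin=af.field.origin + shift,
        )
        out.append(ArchetypeField(coarse, af.origin_offset_um + shift,
                                  af.n_iterations, af.converged))
    return out


def itm_field(model: TumourModel, coarse_fields: list[ArchetypeField],
              coarse_spacing: float = 100.0,
              origin: np.ndarray | None = None,
              shape: tuple[int, int, int] | None = None) -> OxygenField:
    """Individual Tree Method: paste every leaf's precomputed coarse field
    at its attachment point (nearest coarse voxel) and keep, per voxel, the
    highest contribution. Voxels reached by no field stay at zero.

    The grid defaults to the bounding box of all translated fields; pass
    ``origin``/``shape`` to evaluate a prescribed window (e.g. one sample
    box), in which case out-of-window contributions are clipped.
    """
    if len(coarse_fields) < len(model.micro_library):
        raise ValueError("need one coarse field per archetype")
    offs = [np.rint(cf.origin_offset_um / coarse_spacing).astype(int)
            for cf in coarse_fields]
    shapes = [np.asarray(cf.field.values.shape) for cf in coarse_fields]

    leaf_vox = np.rint(model.leaf_positions / coarse_spacing).astype(int)
    clipping = origin is not None
    if origin is None:
        los = np.array([leaf_vox[i] + offs[int(a)]
                        for i, a in enumerate(model.archetype_ids)])
        his = np.array([leaf_vox[i] + offs[int(a)] + shapes[int(a)]
                        for i, a in enumerate(model.archetype_ids)])
        lo_all = los.min(axis=0)
        hi_all = his.max(axis=0)
        shape = tuple(hi_all - lo_all)
        origin = lo_all * coarse_spacing
    else:
        origin = np.asarray(origin, dtype=float)
        lo_all = np.rint(origin / coarse_spacing).astype(int)
    shape_arr = np.asarray(shape, dtype=int)

    out = np.zeros(tuple(shape_arr))
    for i, a in enumerate(model.archetype_ids):
        a = int(a)
        start = leaf_vox[i] + offs[a] - lo_all
        stop = start + shapes[a]
        if np.any(stop <= 0) or np.any(start >= shape_arr):
            if clipping:
                continue
            raise ValueError(f"leaf {i} falls outside the ITM grid")
        s0 = np.maximum(start, 0)
        s1 = np.minimum(stop, shape_arr)
        if np.any(s1 <= s0):
            continue
        dst = tuple(slice(s0[d], s1[d]) for d in range(3))
        src = tuple(slice(s0[d] - start[d], s1[d] - start[d]) for d in range(3))
        np.maximum(out[dst], coarse_fields[a].field.values[src], out=out[dst])
    return OxygenField(values=out,
                       mask=np.zeros(out.shape, dtype=bool),
                       source=np.zeros(out.shape),
                       spacing=coarse_spacing,
                       origin=np.asarray(origin, dtype=float))
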