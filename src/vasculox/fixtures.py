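"""Deterministic synthetic fixtures.

Small trees and fields used throughout the test suites (and handy for
demos), generated on demand from a seed so nothing binary ships with the
package.
"""

from __future__ import annotations

import numpy as np

from .grids import OxygenField
from .raster import rasterize_tree
from .trees import TreeParams, VesselTree, generate_tree, micro_tree_params

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("two-generation-tree", "micro-tree", "single-segment",
                 "two-adjacent-trees", "gaussian-blob")


def _two_generation_tree(seed: int, size: float) -> VesselTree:
    params = TreeParams(
        n_generations=2,
        segment_length_by_generation=[size, 0.6 * size],
        radius_start=30.0,
        radius_decrement_range=(5.0, 10.0),
        length_jitter=0.1,
    )
    return generate_tree(params, rng=np.random.default_rng(seed))


def _micro_tree(seed: int, size: float) -> VesselTree:
    """A small three-generation microvessel-style tree (scaled by size/200)."""
    params = micro_tree_params(
        n_generations=3,
        segment_length_by_generation=np.array([1.0, 0.6, 0.35]) * size,
        radius_start=30.0,
        radius_decrement_range=(5.0, 8.0),
        min_segment_length_um=None,
    )
    return generate_tree(params, rng=np.random.default_rng(seed))


def _single_segment(size: float):
    """One straight vessel segment of length ``size`` μm, radius 15 μm,
    rasterized at 10 μm."""
    n = 2
    tree = VesselTree(
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, size]]),
        radii=np.array([15.0, 15.0]),
        generations=np.array([0, 1]),
        parents=np.array([-1, 0]),
        directions=np.array([[0.0, 0.0, 1.0]] * n),
    )
    return rasterize_tree(tree, spacing=10.0, pad_um=60.0)


def _two_adjacent_trees(seed: int, size: float) -> tuple[VesselTree, VesselTree]:
    """Two trees whose vessel rasters stay disjoint but whose oxygen halos
    overlap (separation ≈ 2.5 tree sizes)."""
    t1 = _micro_tree(seed, size)
    t2 = _micro_tree(seed + 1, size)
    return t1, t2.translated([2.5 * size, 0.0, 0.0])


def _gaussian_blob(size: float, seed: int) -> OxygenField:
    """An analytic isotropic Gaussian of σ = size μm sampled on a 31³ grid
    at 10 μm, peak 100 mmHg at the centre; no vessels."""
    n = 31
    ax = (np.arange(n) - n // 2) * 10.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = 100.0 * np.exp(-(x * x + y * y + z * z) / (2.0 * size ** 2))
    zeros = np.zeros((n, n, n))
    return OxygenField(vals, zeros.astype(bool), zeros, spacing=10.0,
                       origin=np.array([-150.0, -150.0, -150.0]))


def make_fixture(kind: str, size: float = 200.0, seed: int = 0):
    """Build one of the named fixtures.

    kinds: "two-generation-tree" (VesselTree), "micro-tree" (VesselTree),
    "single-segment" (VesselGrid), "two-adjacent-trees" (pair of
    VesselTree), "gaussian-blob" (OxygenField). Same (kind, size, seed)
    always yields the identical object.
    """
    if kind == "two-generation-tree":
        return _two_generation_tree(seed, size)
    if kind == "micro-tree":
        return _micro_tree(seed, size)
    if kind == "single-segment":
        return _single_segment(size)
    if kind == "two-adjacent-trees":
        return _two_adjacent_trees(seed, size)
    if kind == "gaussian-blob":
        return _gaussian_blob(size, seed)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
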