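"""Whole-tumour assembly.

Many macrovessel trees are grown from random seed points; their pooled
leaf coordinates become attachment points for microvessel trees drawn
uniformly from a library of precomputed archetypes. Leaves colliding in
the same coarse occupancy cell are removed (first come, first kept), the
tumour perimeter is the convex hull of the surviving leaves, and the
functional microvessel density is the total archetype field volume per
tumour volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .trees import TreeParams, VesselTree, generate_tree, leaf_positions

__all__ = [
    "TumourModel",
    "SampleSpec",
    "assemble_tumour",
    "remove_overlapping_leaves",
    "hull_and_volume",
    "extract_sample",
    "archetype_extent_volume_mm3",
]

UM3_PER_CM3 = 1e12
UM3_PER_MM3 = 1e9


def archetype_extent_volume_mm3(tree: VesselTree, field_margin_um: float = 100.0) -> float:
    """Volume (mm³) of the axis-aligned box occupied by a microvessel tree's
    oxygen field: the node bounding box inflated by the largest radius plus
    a diffusion margin."""
    lo, hi = tree.bounding_box(margin_um=field_margin_um)
    return float(np.prod(hi - lo)) / UM3_PER_MM3


@dataclass
class TumourModel:
    """Assembled macroscopic tumour.

    ``leaf_positions`` (k, 3) μm are the surviving microtree attachment
    points; each carries the id of its parent macrotree and its randomly
    assigned archetype. ``density`` is the functional microvessel density:
    n_leaves × mean archetype field volume / tumour volume.
    """

    leaf_positions: np.ndarray
    macrotree_ids: np.ndarray
    archetype_ids: np.ndarray
    micro_library: list[VesselTree]
    hull: ConvexHull
    volume_cm3: float
    density: float
    n_removed_overlaps: int
    archetype_volumes_mm3: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.leaf_positions.shape[0]

    def summary(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "n_macrotrees": int(self.macrotree_ids.max()) + 1 if self.n_leaves else 0,
            "n_archetypes": len(self.micro_library),
            "volume_cm3": self.volume_cm3,
            "functional_density": self.density,
            "n_removed_overlaps": self.n_removed_overlaps,
        }

    def save(self, directory: str | Path) -> None:
        """Persist as leaf-registry CSV + OFF hull mesh + JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        pd.DataFrame({
            "x": self.leaf_positions[:, 0],
            "y": self.leaf_positions[:, 1],
            "z": self.leaf_positions[:, 2],
            "macrotree_id": self.macrotree_ids,
            "archetype_id": self.archetype_ids,
        }).to_csv(directory / "leaves.csv", index=False)
        pts = self.hull.points
        faces = self.hull.simplices
        with open(directory / "hull.off", "w") as fh:
            fh.write(f"OFF\n{len(pts)} {len(faces)} 0\n")
            for p in pts:
                fh.write(f"{p[0]} {p[1]} {p[2]}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        with open(directory / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def remove_overlapping_leaves(positions: np.ndarray,
                              order_keys: np.ndarray,
                              cell_size_um: float = 100.0):
    """Keep at most one leaf per occupancy cell of a coarse grid.

    ``order_keys`` is an (k, 2) array of (macrotree id, leaf id); within a
    cell the first leaf in lexicographic key order survives. Returns
    (kept boolean mask, number removed).
    """
    if cell_size_um <= 0:
        raise ValueError("cell_size_um must be positive")
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] == 0:
        return np.zeros(0, dtype=bool), 0
    cells = np.floor(positions / cell_size_um).astype(np.int64)
    order = np.lexsort((order_keys[:, 1], order_keys[:, 0]))
    seen: set[tuple[int, int, int]] = set()
    keep = np.zeros(positions.shape[0], dtype=bool)
    for i in order:
        key = tuple(cells[i])
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return keep, int((~keep).sum())


def hull_and_volume(points: np.ndarray) -> tuple[ConvexHull, float]:
    """Convex-hull triangulation of a point cloud and its volume in the
    units of ``points`` cubed. Degenerate (coplanar or < 4 point) input
    raises."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 4:
        raise ValueError("need at least 4 points for a 3D hull")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (coplanar?): {exc}") from exc
    return hull, float(hull.volume)


def assemble_tumour(n_macrotrees: int,
                    macro_params: TreeParams,
                    micro_library: list[VesselTree],
                    rng: np.random.Generator | int | None = None,
                    seeding_radius_um: float = 10_000.0,
                    cell_size_um: float = 100.0,
                    field_margin_um: float = 100.0) -> TumourModel:
    """Generate macrotrees at random seed points and attach microtree
    archetypes to their leaves.

    Each macrotree gets its own deterministic child RNG stream, so any
    single tree can be regenerated independently of the others.
    """
    if not micro_library:
        raise ValueError("micro_library must contain at least one archetype")
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed_seq = np.random.SeedSequence(rng if rng is not None else 0)
    else:
        seed_seq = rng.bit_generator.seed_seq.spawn(1)[0]
    tree_seeds = seed_seq.spawn(n_macrotrees + 1)
    assign_rng = np.random.default_rng(tree_seeds[-1])

    all_pos, all_tree_id, all_leaf_id = [], [], []
    for i in range(n_macrotrees):
        trng = np.random.default_rng(tree_seeds[i])
        # uniform point in the seeding ball, isotropic launch direction
        while True:
            p = trng.uniform(-1.0, 1.0, 3)
            if p @ p <= 1.0:
                break
        root = p * seeding_radius_um
        d = trng.normal(size=3)
        d /= np.linalg.norm(d)
        tree = generate_tree(macro_params, root_position=root,
                             root_direction=d, rng=trng)
        lp = leaf_positions(tree)
        all_pos.append(lp)
        all_tree_id.append(np.full(lp.shape[0], i))
        all_leaf_id.append(np.arange(lp.shape[0]))
    positions = np.concatenate(all_pos)
    tree_ids = np.concatenate(all_tree_id)
    leaf_ids = np.concatenate(all_leaf_id)

    keep, n_removed = remove_overlapping_leaves(
        positions, np.column_stack([tree_ids, leaf_ids]), cell_size_um)
    positions, tree_ids = positions[keep], tree_ids[keep]
    archetype_ids = assign_rng.integers(0, len(micro_library), positions.shape[0])

    hull, vol_um3 = hull_and_volume(positions)
    vols = np.array([archetype_extent_volume_mm3(t, field_margin_um)
                     for t in micro_library])
    volume_cm3 = vol_um3 / UM3_PER_CM3
    density = positions.shape[0] * float(vols.mean()) / (vol_um3 / UM3_PER_MM3)
    return TumourModel(
        leaf_positions=positions,
        macrotree_ids=tree_ids,
        archetype_ids=archetype_ids,
        micro_library=micro_library,
        hull=hull,
        volume_cm3=volume_cm3,
        density=density,
        n_removed_overlaps=n_removed,
        archetype_volumes_mm3=vols,
    )


@dataclass
class SampleSpec:
    """A cubic sub-volume of the tumour and the microtrees whose oxygen
    fields can reach it (archetype bounding box vs padded box test)."""

    centre_um: np.ndarray
    side_um: float
    pad_um: float
    leaf_positions: np.ndarray     # (m, 3)
    archetype_ids: np.ndarray      # (m,)
    micro_library: list[VesselTree]

    @property
    def n_trees(self) -> int:
        return self.leaf_positions.shape[0]

    def trees(self):
        """Yield each selected microtree translated to its attachment point."""
        for pos, aid in zip(self.leaf_positions, self.archetype_ids):
            yield self.micro_library[int(aid)].translated(pos)


def _points_in_hull(hull: ConvexHull, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    eq = hull.equations  # (f, 4): normal · x + offset <= 0 inside
    return np.all(pts @ eq[:, :3].T + eq[:, 3] <= tol, axis=1)


def extract_sample(model: TumourModel, centre_um, side_um: float,
                   pad_um: float = 150.0,
                   field_margin_um: float = 100.0) -> SampleSpec:
    """Select the microtrees whose fields intersect a padded cubic sample.

    The unpadded box must lie inside the tumour hull; selection tests every
    leaf's archetype bounding box against the padded box.
    """
    centre = np.asarray(centre_um, dtype=float)
    half = side_um / 2.0
    corners = centre + half * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    if not np.all(_points_in_hull(model.hull, corners)):
        raise ValueError("sample box is not contained in the tumour hull")

    lo_box = centre - half - pad_um
    hi_box = centre + half + pad_um
    keep = np.zeros(model.n_leaves, dtype=bool)
    # archetype bounding boxes are root-relative; cache one per archetype
    bboxes = [t.bounding_box(margin_um=field_margin_um) for t in model.micro_library]
    for i in range(model.n_leaves):
        blo, bhi = bboxes[int(model.archetype_ids[i])]
        p = model.leaf_positions[i]
        if np.all(p + bhi >= lo_box) and np.all(p + blo <= hi_box):
            keep[i] = True
    return SampleSpec(
        centre_um=centre, side_um=float(side_um), pad_um=float(pad_um),
        leaf_positions=model.leaf_positions[keep],
        archetype_ids=model.archetype_ids[keep],
        micro_library=model.micro_library,
    )
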