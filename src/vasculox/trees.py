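"""Stochastic generation of bifurcating vessel trees.

A tree grows from a root point by repeated bifurcation: at every branch
point two narrower daughter vessels emerge, their polar angles θ drawn by
inverse-transform sampling from per-branch cumulative distribution tables
and their azimuths ϕ uniform on [0, 2π). Branch-local angles are rotated
into the global frame with direction cosines relative to the parent
segment. The radius shrinks by an independent uniform draw per generation;
segment lengths follow a per-generation schedule with relative jitter.

Two scales use the same machinery: non-permeable macrovessel trees (nine
generations by default, only their leaf coordinates are consumed
downstream) and permeable microvessel trees (five generations, mean
segment lengths 400 → 50 μm, segments shorter than a 40 μm floor
discarded as below the working resolution).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AngleCdf",
    "TreeParams",
    "VesselTree",
    "build_angle_sampler",
    "sample_branch_pair",
    "to_global_frame",
    "generate_tree",
    "leaf_positions",
    "default_angle_cdfs",
    "macro_tree_params",
    "micro_tree_params",
]


# ---------------------------------------------------------------------------
# angle distributions

@dataclass(frozen=True)
class AngleCdf:
    """Tabulated cumulative distribution of a bifurcation polar angle.

    ``theta`` is strictly increasing in [0, π] (radians); ``cum`` is monotone
    non-decreasing from exactly 0 to exactly 1. Sampling inverts the
    piecewise-linear interpolant of this table.
    """

    theta: np.ndarray
    cum: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "cum", np.asarray(self.cum, dtype=float))
        t, c = self.theta, self.cum
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValueError("theta and cum must be 1D arrays of equal length >= 2")
        if t[0] < 0 or t[-1] > np.pi + 1e-12:
            raise ValueError("theta must lie in [0, pi]")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(f"theta not strictly increasing at row {bad[0] + 1}")
        bad = np.nonzero(np.diff(c) < 0)[0]
        if bad.size:
            raise ValueError(f"cumulative probability decreases at row {bad[0] + 1}")
        if c[0] != 0.0 or c[-1] != 1.0:
            raise ValueError("cumulative values must start at 0 and end at 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleCdf":
        """Read a two-column (theta_radians, cumulative_probability) CSV."""
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                try:
                    rows.append((float(row[0]), float(row[1])))
                except ValueError:  # header line
                    continue
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1])


def build_angle_sampler(cdf: AngleCdf) -> Callable[[np.ndarray], np.ndarray]:
    """Return the inverse of the piecewise-linear CDF, u in [0, 1] → θ.

    ``sampler(0)`` is the smallest tabulated angle and ``sampler(1)`` the
    largest; the map is monotone in u.
    """
    cum, theta = cdf.cum, cdf.theta

    def sampler(u):
        return np.interp(u, cum, theta)

    return sampler


# Default tables approximating published hepatic bifurcation statistics:
# branch 1 (the straighter continuation) is concentrated at small polar
# angles, branch 2 deflects more strongly.  Degrees in the comments.
_DEFAULT_BRANCH1 = (
    #  deg      cum
    (0.0, 0.00),
    (10.0, 0.08),
    (20.0, 0.28),
    (30.0, 0.55),
    (40.0, 0.75),
    (50.0, 0.87),
    (60.0, 0.93),
    (80.0, 0.98),
    (120.0, 1.00),
)
_DEFAULT_BRANCH2 = (
    (0.0, 0.00),
    (20.0, 0.05),
    (35.0, 0.20),
    (50.0, 0.45),
    (65.0, 0.68),
    (80.0, 0.84),
    (100.0, 0.95),
    (130.0, 0.99),
    (180.0, 1.00),
)


def default_angle_cdfs() -> tuple[AngleCdf, AngleCdf]:
    """The package's built-in polar-angle tables for the two daughter branches."""
    def make(rows):
        arr = np.asarray(rows, dtype=float)
        return AngleCdf(np.deg2rad(arr[:, 0]), arr[:, 1])
    return make(_DEFAULT_BRANCH1), make(_DEFAULT_BRANCH2)


def sample_branch_pair(
    samplers: Sequence[Callable], rng: np.random.Generator
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Draw local directions (θ, ϕ) for both daughter branches.

    θ of branch i comes from its inverse-CDF sampler; ϕ is uniform on
    [0, 2π). The four underlying uniforms are drawn in a fixed order so a
    seeded generator reproduces the pair exactly.
    """
    u = rng.random(4)
    theta1 = float(samplers[0](u[0]))
    theta2 = float(samplers[1](u[1]))
    phi1 = float(2.0 * np.pi * u[2])
    phi2 = float(2.0 * np.pi * u[3])
    return (theta1, phi1), (theta2, phi2)


def to_global_frame(local_direction: tuple[float, float],
                    parent_direction: np.ndarray) -> np.ndarray:
    """Rotate a branch-local (θ, ϕ) direction into the global frame.

    θ is the deflection from the parent direction, ϕ the azimuth about it.
    The azimuth reference is fixed deterministically from the parent vector
    (the global axis least aligned with it), so the map is reproducible.
    """
    theta, phi = local_direction
    p = np.asarray(parent_direction, dtype=float)
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        raise ValueError("parent direction has zero norm")
    a = p / norm
    # reference axis least aligned with the parent
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(a)))] = 1.0
    e1 = np.cross(ref, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    v = (np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
         + np.cos(theta) * a)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# tree parameters and container

@dataclass
class TreeParams:
    """Everything needed to grow one vessel tree.

    ``segment_length_by_generation`` gives the mean segment length (μm) for
    generations 1..n; the realised length multiplies the mean by a uniform
    factor in [1 − jitter, 1 + jitter]. The radius starts at
    ``radius_start`` and loses an independent uniform draw from
    ``radius_decrement_range`` per generation. If ``min_segment_length_um``
    is set, sampled segments shorter than it are discarded together with
    their subtree (finite-resolution floor for microvessels).
    """

    n_generations: int
    segment_length_by_generation: np.ndarray
    radius_start: float
    radius_decrement_range: tuple[float, float] = (5.0, 15.0)
    length_jitter: float = 0.2
    angle_cdfs: tuple[AngleCdf, AngleCdf] | None = None
    min_segment_length_um: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.segment_length_by_generation = np.asarray(
            self.segment_length_by_generation, dtype=float)
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.segment_length_by_generation.size != self.n_generations:
            raise ValueError("need one mean segment length per generation")
        if np.any(self.segment_length_by_generation <= 0):
            raise ValueError("segment lengths must be positive")
        if self.radius_start <= 0:
            raise ValueError("radius_start must be positive")
        lo, hi = self.radius_decrement_range
        if not (0 <= lo <= hi):
            raise ValueError("radius decrement range must satisfy 0 <= low <= high")
        if not (0 <= self.length_jitter < 1):
            raise ValueError("length_jitter must be in [0, 1)")
        if self.angle_cdfs is None:
            self.angle_cdfs = default_angle_cdfs()


def macro_tree_params(**overrides) -> TreeParams:
    """Default macrovessel parameters: nine generations, geometrically
    shrinking segment lengths (5 mm → ~0.5 mm), starting radius 140 μm with
    5–15 μm per-generation decrement, so end branches are ≈100 μm wide."""
    defaults = dict(
        n_generations=9,
        segment_length_by_generation=5000.0 * 0.75 ** np.arange(9),
        radius_start=140.0,
        radius_decrement_range=(5.0, 15.0),
        length_jitter=0.2,
    )
    defaults.update(overrides)
    return TreeParams(**defaults)


def micro_tree_params(**overrides) -> TreeParams:
    """Default microvessel parameters: five generations, mean lengths
    400 → 50 μm (±20% jitter, so minima reach 40 μm), 40 μm discard floor.
    The decrement range is narrowed so five generations never exhaust the
    50 μm starting radius."""
    defaults = dict(
        n_generations=5,
        segment_length_by_generation=400.0 * (50.0 / 400.0) ** (np.arange(5) / 4.0),
        radius_start=50.0,
        radius_decrement_range=(5.0, 9.0),
        length_jitter=0.2,
        min_segment_length_um=40.0,
    )
    defaults.update(overrides)
    return TreeParams(**defaults)


@dataclass
class VesselTree:
    """Array-of-struct bifurcating tree.

    Node 0 is the root; children are appended generation by generation, so a
    child always has a larger index than its parent. ``directions`` holds the
    unit vector of the segment arriving at each node (the launch direction
    for the root).
    """

    positions: np.ndarray      # (n, 3) μm
    radii: np.ndarray          # (n,) μm
    generations: np.ndarray    # (n,) int, root = 0
    parents: np.ndarray        # (n,) int, -1 for the root
    directions: np.ndarray     # (n, 3) unit vectors

    root_index: int = 0

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_generations(self) -> int:
        return int(self.generations.max())

    @property
    def leaf_indices(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parents[self.parents >= 0]] = True
        return np.nonzero(~has_child)[0]

    def segments(self) -> np.ndarray:
        """(m, 2) array of (parent, child) node index pairs, child-sorted."""
        child = np.nonzero(self.parents >= 0)[0]
        return np.column_stack([self.parents[child], child])

    def segment_lengths(self) -> np.ndarray:
        seg = self.segments()
        return np.linalg.norm(
            self.positions[seg[:, 1]] - self.positions[seg[:, 0]], axis=1)

    def arc_lengths(self) -> np.ndarray:
        """Path distance from the root to every node along the centreline."""
        arc = np.zeros(self.n_nodes)
        for pa, ch in self.segments():   # children sorted after parents
            arc[ch] = arc[pa] + np.linalg.norm(
                self.positions[ch] - self.positions[pa])
        return arc

    def translated(self, offset: np.ndarray) -> "VesselTree":
        return VesselTree(self.positions + np.asarray(offset, dtype=float),
                          self.radii, self.generations, self.parents,
                          self.directions)

    def bounding_box(self, margin_um: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the node cloud inflated by the largest radius
        plus ``margin_um``."""
        pad = float(self.radii.max()) + margin_um
        return self.positions.min(axis=0) - pad, self.positions.max(axis=0) + pad

    def to_table(self):
        """Node table as a pandas DataFrame (id, parent_id, x, y, z, radius_um, generation)."""
        import pandas as pd
        return pd.DataFrame({
            "id": np.arange(self.n_nodes),
            "parent_id": self.parents,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "radius_um": self.radii,
            "generation": self.generations,
        })


def generate_tree(params: TreeParams,
                  root_position: np.ndarray = (0.0, 0.0, 0.0),
                  root_direction: np.ndarray = (0.0, 0.0, 1.0),
                  rng: np.random.Generator | None = None) -> VesselTree:
    """Grow a complete binary tree by iterative sampling.

    Every frontier node spawns two daughters per generation until the
    predetermined generation count is reached; with a fixed seed the result
    is bit-identical across runs. Raises if the radius schedule would hit
    zero before the last generation (the decrement range must be reduced or
    the starting radius increased).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    samplers = (build_angle_sampler(params.angle_cdfs[0]),
                build_angle_sampler(params.angle_cdfs[1]))

    positions = [np.asarray(root_position, dtype=float)]
    rd = np.asarray(root_direction, dtype=float)
    nrm = np.linalg.norm(rd)
    if nrm < 1e-12:
        raise ValueError("root direction has zero norm")
    directions = [rd / nrm]
    radii = [float(params.radius_start)]
    generations = [0]
    parents = [-1]
    frontier = [0]

    lo, hi = params.radius_decrement_range
    jit = params.length_jitter
    for g in range(1, params.n_generations + 1):
        mean_len = params.segment_length_by_generation[g - 1]
        next_frontier = []
        for node in frontier:
            pair = sample_branch_pair(samplers, rng)
            for local in pair:
                length = mean_len * (1.0 + jit * (2.0 * rng.random() - 1.0))
                decrement = rng.uniform(lo, hi)
                if (params.min_segment_length_um is not None
                        and length < params.min_segment_length_um):
                    continue  # below the finite-resolution floor
                radius = radii[node] - decrement
                if radius <= 0:
                    raise ValueError(
                        f"radius reached {radius:.1f} μm at generation {g}; "
                        "increase radius_start or reduce the decrement range")
                direction = to_global_frame(local, directions[node])
                positions.append(positions[node] + length * direction)
                directions.append(direction)
                radii.append(radius)
                generations.append(g)
                parents.append(node)
                next_frontier.append(len(positions) - 1)
        frontier = next_frontier
        if not frontier:
            break
    return VesselTree(
        positions=np.asarray(positions),
        radii=np.asarray(radii),
        generations=np.asarray(generations, dtype=int),
        parents=np.asarray(parents, dtype=int),
        directions=np.asarray(directions),
    )


def leaf_positions(tree: VesselTree) -> np.ndarray:
    """Positions of all childless nodes, (k, 3) μm."""
    return tree.positions[tree.leaf_indices]
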