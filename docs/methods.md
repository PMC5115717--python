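# Methods

## The model

`vasculox` simulates the oxygenation of a macroscopic tumour supplied by a
stochastic vascular tree, and compares two schemes for computing the
whole-tumour oxygen field. The pipeline has four stages.

**1. Vessel-tree generation.** Trees are grown by iterative bifurcation:
from every branch point two narrower daughters emerge. Each daughter's
polar deflection θ from its parent is drawn by inverse-transform sampling
from a per-branch cumulative-distribution table; the azimuth ϕ about the
parent axis is uniform on [0, 2π). Branch-local angles are rotated into
the global frame with direction cosines (a deterministic orthonormal
basis is attached to the parent direction, so results are reproducible).
Segment lengths follow a per-generation schedule with ±20% uniform
jitter; the radius loses an independent uniform draw from a decrement
range per generation.

Two scales share this machinery:

- *Macrovessel trees* (9 generations by default) are non-permeable and
  enter the oxygen computation only through their leaf coordinates, which
  serve as attachment points for microvessel trees.
- *Microvessel trees* (5 generations) are the permeable, oxygen-releasing
  vessels. Mean segment lengths fall from 400 to 50 μm; with the jitter
  the shortest segments reach 40 μm, and segments sampled below that
  floor are discarded together with their subtree, since at 10 μm
  resolution such capillaries would largely overlap their parent vessel.

**2. Rasterization.** Each microvessel segment's centreline is
discretised with a 3-D Bresenham walk (26-connected, no gaps, one voxel
per driving-axis step; driving axis = dominant axis, ties x > y > z) and
dilated by a spherical kernel matching the segment radius (voxel-centre
inclusion test, boundary voxels whose centre lies exactly on the sphere
included). Alongside the binary mask, a path-distance field stores each
vessel voxel's centreline arc length from the root (minimum over
depositing segments).

**3. Oxygen transport.** Every vessel voxel is a Dirichlet source:
arterial pO₂ (100 mmHg) at the tree's feeding point, falling linearly
with path distance to venous pO₂ (40 mmHg) at the most distant vessel
voxel. The tissue field is advanced by explicit Green's-function steps:
one time step t is a convolution with a Gaussian of per-axis standard
deviation σ = √(2·D_O·t) (σ = 20 μm at the defaults), sampled at voxel
centres, truncated at 4σ and renormalised to unit sum so the discrete
operator conserves mass exactly; the analytic normalisation constant is
thereby absorbed and recorded only for reference. Because the Gaussian
factorises across axes, the convolution is carried out as three 1-D
passes with zero-padded boundaries; tests verify bit-level agreement
with dense 3-D convolution. After each diffusion step the vessel voxels
are re-clamped to their source values, then tissue consumption is
subtracted following Michaelis–Menten kinetics, C = C₀·pO₂/(pO₂ + K_M),
clamped at zero (the explicit update t·C₀ = 1.5 mmHg can overshoot near
anoxia). The order within an iteration is diffuse → clamp → consume.
Iteration stops when the relative change of the summed tissue pO₂ stays
below 1e-4 for three consecutive iterations.

**4. Tumour assembly and the two schemes.** Many macrotrees are seeded
uniformly in a ball with isotropic launch directions; their pooled leaves
are deduplicated on a 100 μm occupancy grid (first leaf per cell kept, in
(tree id, leaf id) order), and each surviving leaf receives a microtree
archetype drawn uniformly from a precomputed library. The tumour
perimeter is the convex hull of the surviving leaves; the functional
microvessel density is n_leaves × mean archetype field volume / hull
volume, where an archetype's field volume is its node bounding box
inflated by the largest radius plus a 100 μm diffusion margin.

- *CTM (Combined Tree Method)*: all microtrees reaching a cubic sample
  (archetype bounding box vs padded box test) are rasterized into one
  10 μm grid — colliding vessel voxels take the maximum source — and
  solved jointly; the pad (default 150 μm ≥ 4σ, mirroring the 330³
  vessel vs 300³ oxygen deposited-volume geometry) is cropped afterwards.
- *ITM (Individual Tree Method)*: each archetype is solved once in
  isolation at 10 μm (zero-padded frame, 200 μm margin retained so the
  stored field includes the oxygenated halo), block-mean down-sampled by
  10× to the 100 μm grid, translated to every attachment point
  (nearest-voxel placement) and combined by voxelwise maximum; unreached
  voxels stay anoxic.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| D_O | oxygen diffusion coefficient in tissue | 2000 | μm² s⁻¹ |
| C₀ | oxygen demand at unlimited supply | 15 | mmHg s⁻¹ |
| K_M | Michaelis constant (pO₂ at C = C₀/2) | 1 | mmHg |
| t | time step | 0.1 | s |
| — | arterial / venous vessel pO₂ | 100 / 40 | mmHg |
| — | fine / coarse voxel size | 10 / 100 | μm |
| — | radius decrement per macro generation | U(5, 15) | μm |
| — | macrotree starting radius | 140 | μm |
| — | microtree starting radius / decrement | 50, U(5, 9) | μm |
| — | hypoxia thresholds | 0.01, 1, 5 | mmHg |
| — | histogram resolution | 1 | mmHg |

The time step and voxel size are coupled: σ = √(2·D_O·t) below half a
voxel would produce no resolvable diffusion per step, and the kernel
constructor rejects that combination. The macrotree starting radius of
140 μm makes nine mean decrements of 10 μm land the end branches near
100 μm diameter; the microtree decrement range is narrowed to (5, 9) μm
so five generations cannot exhaust the 50 μm starting radius.

## Defaults the source data do not pin down

The polar-angle tables and the per-generation segment-length schedules
come from experimental hepatic-vasculature branching statistics that are
not reproduced numerically in our sources. The shipped defaults are a
plausible piecewise-linear approximation (branch 1 concentrated at
smaller deflections than branch 2; medians ≈ 29° and 53°) and a
geometric macro length schedule (5 mm shrinking by ×0.75 per
generation). Both are configuration inputs: user-supplied two-column CSV
tables (θ in radians, cumulative probability) and length arrays replace
them without code changes, and every statistical guarantee in the test
suite is stated against whichever table is supplied.

## Evaluation statistics

Hypoxic fractions count voxels strictly below the threshold, over all
voxels of the pad-cropped sample (vessel voxels carry ≥ 40 mmHg, so they
never count at the standard thresholds). Means and SDs are over all
voxels; the SD is the population SD. Distributions are 1 mmHg-resolution
normalized histograms; the RMSD between two distributions is, by
default, the root mean square difference of their *cumulative* curves —
the only convention under which identical distributions give 0 and two
single-bin distributions at opposite ends of a 101-bin range give
√(100/101) ≈ 1; a density-histogram variant is exposed as an option. The
two-sample Kolmogorov–Smirnov statistic is the exact merged-ECDF
sup-distance (no subsampling), with the large-sample rejection rule
D > c(α)·√((n₁+n₂)/(n₁·n₂)), c(0.05) = 1.36, c(0.001) = 1.95.
Correlation matrices are pairwise Pearson r with two-sided t-distributed
p-values (n − 2 df); diagonals and zero-variance pairs are flagged NaN.

## Numerical choices and degenerate inputs

- Dirichlet clamping of vessel voxels after every diffusion step: without
  it the vessels would deplete, contradicting the constant-vessel-oxygen
  assumption of the model.
- A tree reduced to its root rasterizes to a single voxel with path
  distance 0 and receives the arterial value.
- A non-monotone angle CDF is rejected naming the offending row; a
  vessel radius below half a voxel degenerates to a single-voxel kernel
  with a warning; a radius schedule that would hit zero before the last
  generation raises with advice; a sample grid or raster grid beyond the
  addressable size raises with a partitioning hint.
- Bresenham reversal (a↔b) may differ by sub-voxel rounding; both
  directions satisfy the same distance bound.
- Down-sampling crops trailing voxels when the shape is not divisible by
  the factor (block means would otherwise mix in padding).
- Raw volumes are headerless little-endian float32 in column-major order
  with a JSON sidecar; an order flag accommodates foreign row-major data.

## What the synthetic generator does and does not show

The generator realises the study conditions at configurable scale:
default tree counts, generation numbers, physical constants and grid
spacings match the conditions above, and the test suite exercises the
whole-tumour code path at roughly 1/1000 linear density (8 macrotrees of
5 generations, 6 archetypes) purely for tractability. The emulation is
structural, not physiological: there is no haemodynamic flow solution,
no anatomical constraint or collision avoidance between branches, no
vessel permeability model beyond the fixed linear intravascular profile,
and the branching tables are approximations. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery
and the direction of method-comparison effects — not quantitative
agreement with any real tumour.

## The CTM-vs-ITM bias

Because vessel voxels are clamped sources and every update is monotone,
adding vessels can only raise the steady-state field; on a common fine
grid the joint solve dominates the voxelwise maximum of isolated solves.
The ITM's hypoxia underestimate emerges at its coarse grid: a 100 μm
block whose fine voxels are mostly anoxic but contain a perivascular
pocket averages above the hypoxia threshold, and the maximum-combination
of per-tree fields compounds the effect. The packaged four-tree sample
configuration reproduces the underestimate; as a counting effect on
~10³ coarse voxels its magnitude fluctuates between realisations, and
individual seeds can fall either side of zero at the 1 mmHg threshold
while the anoxic-threshold (0.01 mmHg) bias is far more robust.

## Known limitations

- Whole-tumour joint solves at 10 μm are out of reach by design; the CTM
  is a sub-volume method here, as in the deposited data.
- The explicit iterated-convolution scheme is first-order in time; an
  implicit or finite-difference solver is deliberately not provided (a
  dense-convolution oracle lives only in the tests).
- The convergence criterion (relative change of total tissue pO₂) can
  declare steady state while slow far-field transients remain; tighten
  the tolerance for long-range studies.
- Archetype reuse means intra-archetype variability is bounded by the
  library size.
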