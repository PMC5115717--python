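# vasculox

Stochastic tumour vasculature generation and steady-state oxygen
transport simulation, for computational tumour physiologists and
radiobiology modellers who need voxel-level pO₂ maps of macroscopic
(clinically sized) tumours — where hypoxic fractions, not just mean
oxygenation, drive predicted radioresistance.

## What it computes

A tumour's vascular supply is modelled as a forest of bifurcating trees
grown stochastically on two scales. At every branch point two narrower
daughter vessels emerge: their polar deflections θ are drawn by
inverse-transform sampling from per-branch cumulative-distribution
tables, azimuths ϕ are uniform on [0, 2π), and branch-local angles are
rotated to the global frame with direction cosines. Macrovessel trees
(9 generations) provide the scaffold; a microvessel tree (5 generations,
segment lengths 400 → 40 μm) is attached at each macrotree leaf.
Microvessels are voxelized at 10 μm with a 3-D Bresenham walk plus
spherical dilation, and each vessel voxel is a Dirichlet oxygen source:
100 mmHg (arterial) at the feeding point falling linearly with
centreline path distance to 40 mmHg (venous) at the most distant voxel.

Tissue oxygen obeys the diffusion equation with Michaelis–Menten
consumption. One explicit time step t is a convolution with the
diffusion Green's function — a Gaussian with per-axis σ = √(2·D_O·t) —
followed by re-clamping the vessel sources and subtracting

    C = C₀ · pO₂ / (pO₂ + K_M)

per voxel (defaults D_O = 2000 μm²/s, C₀ = 15 mmHg/s, K_M = 1 mmHg,
t = 0.1 s). Iteration continues until the total tissue pO₂ is
stationary.

Two whole-tumour schemes are implemented and compared:

- **CTM** (Combined Tree Method) — all microtrees reaching a cubic
  sample are solved *jointly* at 10 μm on a padded grid (pad cropped
  afterwards); captures inter-tree interaction.
- **ITM** (Individual Tree Method) — each archetype tree is solved once
  in isolation, block-mean down-sampled to a 100 μm grid, translated to
  every attachment point and max-combined; cheap enough for a whole
  tumour, but blind to interaction.

The evaluation module quantifies the comparison: hypoxic fractions
HF_0.01 / HF_1 / HF_5 (voxels below 0.01, 1, 5 mmHg), vascular fraction,
mean and SD of pO₂, RMSD between cumulative 1 mmHg-resolution pO₂
distributions, exact two-sample Kolmogorov–Smirnov tests with the
large-sample criterion D > c(α)·√((n₁+n₂)/(n₁·n₂)), and Pearson
correlation matrices of per-sample properties.

## Worked example

```python
import numpy as np
import vasculox as vx

# one microvessel tree: 5 generations, mean segment lengths 400 -> 50 um
tree = vx.generate_tree(vx.micro_tree_params(), rng=np.random.default_rng(1))
print(tree.n_nodes, tree.leaf_indices.size)        # 63 32
print(round(tree.segment_lengths().min(), 1))      # 40.9  (>= 40 um floor)

# rasterize, assign vessel pO2, solve to steady state
res = vx.solve_single_tree(tree, vx.PhysParams(), spacing=10.0, pad_um=150.0)
print(res.n_iterations, res.converged)             # 57 True

d = vx.distribution(res.field)                     # 1 mmHg histogram
print({k: round(v, 4) for k, v in d.as_dict().items() if v is not None})
# {'HF_0.01': 0.9227, 'HF_1': 0.9405, 'HF_5': 0.9586,
#  'mean_pO2': 1.1846, 'sd_pO2': 7.1385}
```

The tree is a complete binary tree (63 nodes, 32 leaves) whose shortest
segment respects the 40 μm finite-resolution floor. The solve converges
in 57 iterations; in the resulting field ~94% of the surrounding box is
below 1 mmHg — a single isolated microtree oxygenates only a thin
perivascular halo, which is why whole-tumour oxygenation hinges on how
the contributions of ~10⁵ trees are combined.

The same machinery scales up through `assemble_tumour` (macrotree
forest, leaf dedup, convex-hull volume, functional density
n_leaves × mean tree field volume / tumour volume), `extract_sample`,
`ctm_field` and `itm_field`. A thin CLI mirrors the library:
`vasculox generate-trees | assemble-tumour | solve-ctm | solve-itm |
evaluate | compare | reproduce-tables`.

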