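"""Tree generation: inverse-transform angle sampling, frame rotation,
binary-tree growth invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasculox as vx
from vasculox.trees import AngleCdf, TreeParams


def uniform_cdf():
    return AngleCdf([0.0, np.pi], [0.0, 1.0])


class TestAngleSampler:
    @pytest.mark.parametrize("cdf,u,expected", [
        (uniform_cdf(), 0.5, np.pi / 2),                      # linear inverse
        (uniform_cdf(), 0.0, 0.0),                            # lower boundary
        (AngleCdf([0.0, np.pi / 4, np.pi], [0.0, 0.8, 1.0]),
         0.4, np.pi / 8),                                     # piecewise inverse
        (AngleCdf([0.1, np.pi], [0.0, 1.0]), 0.0, 0.1),       # θ_min respected
        (AngleCdf([0.1, np.pi], [0.0, 1.0]), 1.0, np.pi),     # θ_max respected
    ])
    def test_inverse_values(self, cdf, u, expected):
        assert vx.build_angle_sampler(cdf)(u) == pytest.approx(expected)

    def test_sampler_monotone_in_u(self):
        cdf = AngleCdf([0.0, 0.4, 1.1, np.pi], [0.0, 0.3, 0.8, 1.0])
        s = vx.build_angle_sampler(cdf)
        u = np.linspace(0, 1, 101)
        assert np.all(np.diff(s(u)) >= 0)

    def test_decreasing_cumulative_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 2"):
            AngleCdf([0.0, 0.5, 0.8, np.pi], [0.0, 0.7, 0.6, 1.0])

    def test_non_monotone_theta_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AngleCdf([0.0, 0.5, 0.4], [0.0, 0.5, 1.0])

    def test_endpoints_enforced(self):
        with pytest.raises(ValueError, match="start at 0"):
            AngleCdf([0.0, np.pi], [0.1, 1.0])

    def test_csv_round_trip(self, tmp_path):
        cdf, _ = vx.default_angle_cdfs()
        p = tmp_path / "cdf.csv"
        p.write_text("theta_radians,cumulative_probability\n" + "\n".join(
            f"{t},{c}" for t, c in zip(cdf.theta, cdf.cum)))
        back = AngleCdf.from_csv(p)
        np.testing.assert_allclose(back.theta, cdf.theta)
        np.testing.assert_allclose(back.cum, cdf.cum)


class TestBranchPairSampling:
    def test_fixed_seed_reproduces_pairs(self):
        cdfs = vx.default_angle_cdfs()
        samplers = [vx.build_angle_sampler(c) for c in cdfs]
        a = vx.sample_branch_pair(samplers, np.random.default_rng(7))
        b = vx.sample_branch_pair(samplers, np.random.default_rng(7))
        assert a == b

    def test_polar_draws_follow_input_cdf(self):
        # Glivenko–Cantelli: the empirical CDF of many draws converges to
        # the supplied table
        cdf = vx.default_angle_cdfs()[0]
        samplers = [vx.build_angle_sampler(c) for c in vx.default_angle_cdfs()]
        rng = np.random.default_rng(123)
        draws = np.array([vx.sample_branch_pair(samplers, rng)[0][0]
                          for _ in range(20000)])
        grid = np.linspace(0, cdf.theta[-1], 300)
        emp = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
        ref = np.interp(grid, cdf.theta, cdf.cum)
        assert np.max(np.abs(emp - ref)) < 0.02

    def test_azimuth_uniform_moment(self):
        samplers = [vx.build_angle_sampler(c) for c in vx.default_angle_cdfs()]
        rng = np.random.default_rng(5)
        phis = np.array([vx.sample_branch_pair(samplers, rng)[0][1]
                         for _ in range(20000)])
        assert phis.min() >= 0 and phis.max() < 2 * np.pi
        se = (2 * np.pi / np.sqrt(12)) / np.sqrt(phis.size)
        assert abs(phis.mean() - np.pi) < 3 * se


class TestGlobalFrame:
    def test_zero_deflection_returns_parent(self):
        for phi in (0.0, 1.0, 3.0):
            np.testing.assert_allclose(
                vx.to_global_frame((0.0, phi), [0, 0, 1]), [0, 0, 1],
                atol=1e-12)

    def test_right_angle_is_orthogonal(self):
        v = vx.to_global_frame((np.pi / 2, 0.0), [0, 0, 1])
        assert abs(v @ [0, 0, 1]) < 1e-12
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_deflection_angle_matches_rotation_oracle(self):
        # independent oracle: the parent·result dot product must equal cos θ
        # for any axis built by an explicit Rodrigues rotation
        rng = np.random.default_rng(11)
        for _ in range(50):
            parent = rng.normal(size=3)
            parent /= np.linalg.norm(parent)
            theta = rng.uniform(0, np.pi)
            phi = rng.uniform(0, 2 * np.pi)
            v = vx.to_global_frame((theta, phi), parent)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
            assert v @ parent == pytest.approx(np.cos(theta), abs=1e-9)

    def test_dot_product_identity_example(self):
        v = vx.to_global_frame((np.pi / 3, np.pi / 4), [1.0, 0, 0])
        assert v @ [1.0, 0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError, match="zero norm"):
            vx.to_global_frame((0.3, 0.1), [0.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(0, np.pi), phi=st.floats(0, 2 * np.pi),
           seed=st.integers(0, 10_000))
    def test_unit_norm_and_angle_property(self, theta, phi, seed):
        parent = np.random.default_rng(seed).normal(size=3)
        if np.linalg.norm(parent) < 1e-6:
            return
        v = vx.to_global_frame((theta, phi), parent)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
        cos = np.clip(v @ (parent / np.linalg.norm(parent)), -1, 1)
        assert np.arccos(cos) == pytest.approx(theta, abs=1e-6)


def small_params(**kw):
    defaults = dict(n_generations=3,
                    segment_length_by_generation=[100.0, 60.0, 40.0],
                    radius_start=40.0, radius_decrement_range=(5.0, 9.0))
    defaults.update(kw)
    return TreeParams(**defaults)


class TestGenerateTree:
    @pytest.mark.parametrize("n_gen,n_leaves,n_nodes", [
        (1, 2, 3),
        (3, 8, 15),
    ])
    def test_complete_binary_tree_counts(self, n_gen, n_leaves, n_nodes):
        params = small_params(
            n_generations=n_gen,
            segment_length_by_generation=[100.0] * n_gen)
        tree = vx.generate_tree(params, rng=np.random.default_rng(0))
        assert tree.n_nodes == n_nodes
        assert tree.leaf_indices.size == n_leaves
        assert vx.leaf_positions(tree).shape == (n_leaves, 3)

    def test_nine_generations_give_512_leaves(self):
        tree = vx.generate_tree(vx.macro_tree_params(),
                                rng=np.random.default_rng(1))
        assert tree.leaf_indices.size == 512

    def test_fixed_decrement_telescopes(self):
        params = small_params(n_generations=5,
                              segment_length_by_generation=[50.0] * 5,
                              radius_start=100.0,
                              radius_decrement_range=(10.0, 10.0))
        tree = vx.generate_tree(params, rng=np.random.default_rng(2))
        np.testing.assert_allclose(tree.radii[tree.leaf_indices], 50.0)

    def test_deterministic_under_seed(self):
        p = small_params()
        a = vx.generate_tree(p, rng=np.random.default_rng(9))
        b = vx.generate_tree(p, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.radii, b.radii)

    def test_radius_exhaustion_raises(self):
        p = small_params(radius_start=10.0, radius_decrement_range=(5.0, 9.0))
        with pytest.raises(ValueError, match="radius_start"):
            vx.generate_tree(p, rng=np.random.default_rng(0))

    def test_structure_invariants(self):
        tree = vx.generate_tree(small_params(), rng=np.random.default_rng(4))
        # exactly one root; parents precede children; generation steps by 1
        assert np.count_nonzero(tree.parents == -1) == 1
        child = np.nonzero(tree.parents >= 0)[0]
        assert np.all(tree.parents[child] < child)   # acyclic by construction
        assert np.all(tree.generations[child]
                      == tree.generations[tree.parents[child]] + 1)
        # binary branching: every internal node has exactly two children
        counts = np.bincount(tree.parents[child], minlength=tree.n_nodes)
        internal = np.setdiff1d(np.arange(tree.n_nodes), tree.leaf_indices)
        assert np.all(counts[internal] == 2)
        # radii non-increasing root → leaf
        assert np.all(tree.radii[child] < tree.radii[tree.parents[child]])
        # all stored directions unit norm
        np.testing.assert_allclose(
            np.linalg.norm(tree.directions, axis=1), 1.0, atol=1e-9)

    def test_leaf_positions_subset_of_nodes(self):
        tree = vx.generate_tree(small_params(), rng=np.random.default_rng(5))
        lp = vx.leaf_positions(tree)
        assert all(any(np.array_equal(p, q) for q in tree.positions) for p in lp)

    def test_micro_trees_respect_length_floor(self):
        # segments below the 40 μm finite-resolution floor are discarded
        for seed in range(5):
            tree = vx.generate_tree(vx.micro_tree_params(),
                                    rng=np.random.default_rng(seed))
            assert tree.segment_lengths().min() >= 40.0

    def test_discard_floor_prunes_subtrees(self):
        p = small_params(min_segment_length_um=95.0,
                         segment_length_by_generation=[100.0] * 3)
        tree = vx.generate_tree(p, rng=np.random.default_rng(3))
        assert tree.n_nodes < 15              # some branches pruned
        assert tree.segment_lengths().min() >= 95.0
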