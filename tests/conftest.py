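import numpy as np
import pytest

import vasculox as vx


@pytest.fixture(scope="session")
def phys():
    return vx.PhysParams()


@pytest.fixture(scope="session")
def micro_tree():
    return vx.make_fixture("micro-tree", size=150.0, seed=3)


@pytest.fixture(scope="session")
def single_segment_grid():
    return vx.make_fixture("single-segment", size=200.0)


@pytest.fixture(scope="session")
def solved_single_tree(phys, micro_tree):
    """Steady-state field of one small microtree, reused by several suites."""
    return vx.solve_single_tree(micro_tree, phys, spacing=10.0, pad_um=120.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160)
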