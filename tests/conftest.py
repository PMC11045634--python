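import numpy as np
import pytest

from metastasim import make_grid, ScalarField


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid3():
    """Small 3-D grid on the default domain."""
    return make_grid([(-0.05, 0.05)] * 3, (8, 8, 8))


@pytest.fixture
def grid2():
    return make_grid([(-0.05, 0.05)] * 2, (16, 16))


@pytest.fixture
def grid1():
    return make_grid([(0.0, 1.0)], (64,))


def random_field(grid, rng, lo=0.0, hi=1.0):
    return ScalarField(grid, rng.uniform(lo, hi, size=grid.shape))
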