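import numpy as np
import pytest

import cardiowave as cw


@pytest.fixture(scope="session")
def params():
    return cw.IonicParams.default()


@pytest.fixture(scope="session")
def rest(params):
    return cw.find_rest_state(params)


@pytest.fixture
def small_grid():
    return cw.Grid2D(nx=16, ny=12)


@pytest.fixture
def iso_weights(small_grid):
    tensor = cw.tensor_from_fibers(0.0, 0.001, 0.001)
    return cw.stencil_weights(tensor, small_grid)


def rng_grid(shape, seed, lo=-90.0, hi=20.0):
    return np.random.default_rng(seed).uniform(lo, hi, shape)
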