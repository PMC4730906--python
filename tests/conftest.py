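import numpy as np
import pytest

from circtrack import build_grid, default_grid, default_prior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def harness_grid():
    return default_grid()


@pytest.fixture(scope="session")
def harness_prior(harness_grid):
    return default_prior(harness_grid)


@pytest.fixture
def tiny_grid():
    # 3 mean directions x 3 concentrations: small enough for exact
    # path enumeration
    return build_grid(3, 4.0, kappa_spacing="linear")
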