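import numpy as np
import pytest

from tetherkin.mpdpde import RadialGrid


@pytest.fixture(scope="session")
def default_grid():
    return RadialGrid()


@pytest.fixture(scope="session")
def fit_grid():
    return RadialGrid(r_max=5.0, n_nodes=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
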