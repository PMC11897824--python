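import numpy as np
import pytest

from oxispec import load_extinction_table, make_lamp_spectrum


@pytest.fixture(scope="session")
def extinction():
    return load_extinction_table()


@pytest.fixture(scope="session")
def grid():
    return np.arange(500.0, 601.0, 1.0)


@pytest.fixture()
def lamp(grid):
    return make_lamp_spectrum(grid, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
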