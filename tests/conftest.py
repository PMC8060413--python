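import numpy as np
import pytest

from spintrace import make_grid
from spintrace.dipolar import default_time_grid


@pytest.fixture(scope="session")
def rgrid():
    return make_grid(1.5, 8.0, 128)


@pytest.fixture(scope="session")
def tgrid():
    return default_time_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
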