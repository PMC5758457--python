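import numpy as np
import pytest

from artdecision import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_draw(params):
    return params.baseline_draw()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
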