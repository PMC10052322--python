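import numpy as np
import pytest

from opikin.grid import OpinionGrid


@pytest.fixture(scope="session")
def grid201():
    return OpinionGrid(201)


@pytest.fixture(scope="session")
def grid101():
    return OpinionGrid(101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
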