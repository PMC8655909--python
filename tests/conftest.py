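import numpy as np
import pytest

from rnadsorb import fragments


@pytest.fixture(scope="session")
def s1_wiss():
    return fragments.make_fragment("S1", structured=True, seed=1)


@pytest.fixture(scope="session")
def s1_noss():
    return fragments.make_fragment("S1", structured=False, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
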