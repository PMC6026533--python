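import numpy as np
import pytest

from linkbal import AdditiveScheme, MultiplicativeScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def additive():
    return AdditiveScheme(s=0.005)


@pytest.fixture
def multiplicative():
    return MultiplicativeScheme.from_het_advantage(0.005)
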