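import numpy as np
import pytest

from mlsisr.analysis import find_fixed_point
from mlsisr.params import NeuronParams


@pytest.fixture(scope="session")
def params():
    return NeuronParams()


@pytest.fixture(scope="session")
def fixed_point(params):
    return find_fixed_point(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
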