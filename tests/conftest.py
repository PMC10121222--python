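import numpy as np
import pytest

from tepsim import (
    JRParams, SyntheticSpec, synthetic_connectome, synthetic_leadfield,
    synthetic_stimulus,
)
from tepsim.synthetic import SMALL_NETWORK_G


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_regions=14, n_channels=8, seed=11)


@pytest.fixture(scope="session")
def small_graph(small_spec):
    return synthetic_connectome(small_spec)


@pytest.fixture(scope="session")
def small_leadfield(small_graph):
    return synthetic_leadfield(8, small_graph, seed=12)


@pytest.fixture(scope="session")
def small_stimulus(small_graph):
    return synthetic_stimulus(small_graph, seed=13)


@pytest.fixture(scope="session")
def jr_default():
    return JRParams(g=SMALL_NETWORK_G)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
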