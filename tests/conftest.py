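import numpy as np
import pytest

from caru.engine import ChannelPopulation, RateSpec
from caru.parameters import CellParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return CellParameters()


@pytest.fixture
def two_state():
    """A<->B with k12=0.3, k21=0.1; equilibrium B = 0.75."""
    return RateSpec(("A", "B"), edges=[(0, 1), (1, 0)], rates=[0.3, 0.1])


@pytest.fixture
def three_state():
    """Three-state scheme with competing transitions out of B."""
    return RateSpec(
        ("A", "B", "C"),
        edges=[(0, 1), (1, 0), (1, 2), (2, 1)],
        rates=[0.4, 0.2, 0.3, 0.1],
    )


@pytest.fixture
def pop_a(two_state):
    return ChannelPopulation.stochastic_init(two_state.state_names, 1000, "A")
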