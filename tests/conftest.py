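import numpy as np
import pytest

from llps_gsa.model import FieldState, ModelParameters
from llps_gsa.simulate import GridSpec, InitialConditionSpec


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def small_grid():
    return GridSpec(nx=32, length=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_admissible_state(rng, shape=(32, 32), h=2.5 / 32,
                            lo=0.05, hi=0.4):
    """A random field state safely inside the admissible set."""
    K1 = rng.uniform(lo, hi, shape)
    K2 = rng.uniform(lo, hi, shape)
    P = rng.uniform(0.1, 0.3, shape)
    R1 = rng.uniform(0.05, 0.2, shape)
    R2 = rng.uniform(0.05, 0.2, shape)
    return FieldState(K1=K1, K2=K2, P=P, R1=R1, R2=R2, h=h)


@pytest.fixture
def random_state(rng):
    return random_admissible_state(rng)
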