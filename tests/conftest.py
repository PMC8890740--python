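import numpy as np
import pytest

from antraft.core import SimParams, init_state
from antraft.io_cli import make_fixture


@pytest.fixture(scope="session")
def units():
    from antraft.core import UnitSystem
    return UnitSystem()


@pytest.fixture()
def small_params():
    return SimParams(A=1.36, seed=7, init_radius=4.0)


@pytest.fixture()
def small_state(small_params):
    return init_state(small_params, seed=7)


@pytest.fixture(scope="session")
def disc10():
    return make_fixture("disc10")


@pytest.fixture(scope="session")
def arm_state():
    return make_fixture("arm")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
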