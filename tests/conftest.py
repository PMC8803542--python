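import numpy as np
import pytest

from motordcm.schedule import generate_schedule
from motordcm.dcm.model import (ConnectivityModel, DCMStructure,
                                HemodynamicConstants, PriorSpec, build_inputs)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(1)


@pytest.fixture(scope="session")
def constants():
    return HemodynamicConstants()


@pytest.fixture(scope="session")
def stable_model():
    """The package's default group-mean connectivity (stable by check)."""
    from motordcm.synth import default_baseline
    return default_baseline()


@pytest.fixture(scope="session")
def exp1_inputs(schedule):
    return build_inputs(schedule, dt=2.0 / 16.0)


@pytest.fixture(scope="session")
def full_structure():
    return DCMStructure.full()


@pytest.fixture(scope="session")
def default_priors(full_structure):
    return PriorSpec.default(full_structure)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
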