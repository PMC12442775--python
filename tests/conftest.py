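import pytest
from hypothesis import settings

from oacbenefit import fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """The default calibrated parameter set."""
    return fixtures.default_parameters()


@pytest.fixture(scope="session")
def zero_event():
    return fixtures.zero_event_parameters()


@pytest.fixture(scope="session")
def no_effect():
    return fixtures.no_effect_parameters()


@pytest.fixture(scope="session")
def certain_death():
    return fixtures.certain_death_parameters()


@pytest.fixture(scope="session")
def unit_utility():
    return fixtures.unit_utility_parameters()
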