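import pytest
from hypothesis import settings

from chestpain_cea.params import load_parameters, resolve_scenario

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def base_case(params):
    return resolve_scenario(params, "base_case")


@pytest.fixture(scope="session")
def conservative(params):
    return resolve_scenario(params, "conservative")
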