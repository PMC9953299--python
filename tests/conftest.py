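import pytest
from hypothesis import settings

import vitd_balance as v

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def male():
    return v.get_preset("male")


@pytest.fixture(scope="session")
def female():
    return v.get_preset("female")


@pytest.fixture(scope="session")
def baseline_result():
    """Long baseline run reaching steady state, shared across tests."""
    cfg = v.scenario_preset("baseline", duration=240.0, step=0.02)
    return v.simulate(cfg)


@pytest.fixture(scope="session")
def surge_result():
    """Infection-surge run with a strong transient, shared across tests."""
    cfg = v.scenario_preset("infection_surge", duration=240.0, step=0.05)
    return v.simulate(cfg)
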