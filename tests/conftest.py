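"""Shared fixtures: expensive simulations are run once per session."""

import pytest

from adcpbpk import AdcPbpkModel, build_regimen


@pytest.fixture(scope="session")
def rat_model():
    return AdcPbpkModel(species="rat")


@pytest.fixture(scope="session")
def human_model():
    return AdcPbpkModel(species="human")


@pytest.fixture(scope="session")
def rat_single(rat_model):
    """Rat, 10 mg/kg single IV bolus, 42 days."""
    return rat_model.simulate(build_regimen("single", 10.0), 42.0)


@pytest.fixture(scope="session")
def human_q3w(human_model):
    """Human, 2.4 mg/kg Q3W x 3 cycles, 63 days."""
    return human_model.simulate(build_regimen("Q3W", 2.4, 3), 63.0)
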