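import pytest

import nursecast as nc


@pytest.fixture(scope="session")
def model() -> nc.ModelParams:
    """Calibrated synthetic model (seed 0): the default study conditions."""
    return nc.make_model(seed=0)


@pytest.fixture(scope="session")
def ledger_a(model):
    return nc.run_scenario(nc.scenario("A"), model)


@pytest.fixture(scope="session")
def ledger_b(model):
    return nc.run_scenario(nc.scenario("B"), model)


@pytest.fixture(scope="session")
def ledger_c(model):
    return nc.run_scenario(nc.scenario("C"), model)
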