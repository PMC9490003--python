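import numpy as np
import pytest

import psmcea


@pytest.fixture(scope="session")
def config():
    return psmcea.default_config()


@pytest.fixture(scope="session")
def model(config):
    return psmcea.CEModel(config)


@pytest.fixture(scope="session")
def base_result(model):
    return model.base_case()


@pytest.fixture(scope="session")
def sim_trial(config):
    """One seeded synthetic trial at the default study conditions."""
    sim = psmcea.TrialSimConfig.from_config(config)
    return psmcea.simulate_trial(sim, seed=20_001)


@pytest.fixture(scope="session")
def os_ipd(sim_trial, config):
    return {arm: sim_trial[(arm, "os")] for arm in config.arm_names}
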