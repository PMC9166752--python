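import numpy as np
import pytest

from feosim import ModelParams, build_preset
from feosim.model import simulate


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def three_meal_protocol():
    return build_preset("three_meal")


@pytest.fixture(scope="session")
def short_three_meal():
    """Desk-scale 3-meal protocol: 6 entrainment days + 60 h deprivation."""
    return build_preset("three_meal", days=6, deprivation_h=60.0)


@pytest.fixture(scope="session")
def short_three_meal_run(params, short_three_meal):
    """One simulation of the short 3-meal protocol, shared across tests."""
    return simulate(params, short_three_meal, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
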