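import numpy as np
import pytest

from plantdeb.environment import make_scenario
from plantdeb.root_shoot import PlantParams, PlantState
from plantdeb.sim_engine import SolverSettings


@pytest.fixture(scope="session")
def plant_params() -> PlantParams:
    return PlantParams()


@pytest.fixture()
def plant_state() -> PlantState:
    return PlantState()


@pytest.fixture(scope="session")
def balanced_env():
    """Constant, resource-replete environment at the reference temperature."""
    return make_scenario(
        "constant", dict(co2=4.0, light=4.0, soil_n=4.0, temperature=293.15)
    )


@pytest.fixture(scope="session")
def zero_env():
    return make_scenario(
        "constant", dict(co2=0.0, light=0.0, soil_n=0.0, temperature=293.15)
    )


@pytest.fixture()
def short_settings() -> SolverSettings:
    return SolverSettings(t_span=(0.0, 50.0), record_every=1.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
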