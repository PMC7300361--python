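import numpy as np
import pytest
from hypothesis import settings

from nitrosip import GuildParams, SimConfig, SoilScenario

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture
def noise_free_config():
    return SimConfig(seed=7, qpcr_cv=0.0, chem_cv=0.0)


@pytest.fixture
def single_guild():
    return GuildParams("AOA", 1e7, 0.1, 0.1, gc_content=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_scenario(**overrides) -> SoilScenario:
    """One-soil scenario with sensible defaults for targeted dynamics tests."""
    defaults = dict(
        soil_id="T",
        native_ph=6.5,
        modified_ph=4.5,
        mineralization_rate=2.0,
        buffer_capacity=100.0,
        initial_nh4=20.0,
        initial_nox=5.0,
        guilds=(GuildParams("AOA", 1e6, 0.05, 0.02),),
    )
    defaults.update(overrides)
    return SoilScenario(**defaults)
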