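import pytest
from hypothesis import HealthCheck, settings

from pterisk import risk_model as rm
from pterisk import synthetic_data as sd

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def adult():
    return rm.ReceptorProfile(group="adult", body_weight=70.0,
                              exposure_duration=10.0, skin_area=5700.0)


@pytest.fixture(scope="session")
def child():
    return rm.ReceptorProfile(group="child", body_weight=25.0,
                              exposure_duration=6.0, skin_area=2800.0)


@pytest.fixture(scope="session")
def adult_constants():
    return rm.default_constants("adult")


@pytest.fixture(scope="session")
def child_constants():
    return rm.default_constants("child")


@pytest.fixture(scope="session")
def toxicity():
    return rm.default_toxicity()


@pytest.fixture(scope="session")
def concentration_panel():
    """Default synthetic seasonal panel (6 sites × 7 days × 2 seasons)."""
    return sd.generate_concentrations(sd.ConcentrationScenario(seed=11))


@pytest.fixture(scope="session")
def survey():
    return sd.generate_survey(sd.PopulationSpec(seed=11))
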