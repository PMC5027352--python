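import pytest
from hypothesis import HealthCheck, settings

from steadycirc import SCENARIOS, apply_scenario, build_reference_model, steady_state

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_model()


@pytest.fixture(scope="session", params=sorted(SCENARIOS))
def scenario_name(request):
    return request.param


@pytest.fixture(scope="session")
def scenario_models(reference_model):
    return {
        name: apply_scenario(reference_model, name) for name in sorted(SCENARIOS)
    }


@pytest.fixture(scope="session")
def scenario_states(scenario_models):
    return {name: steady_state(m) for name, m in scenario_models.items()}
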