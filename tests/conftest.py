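import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    from mitoscribe.simulate import SimConfig

    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def organelles(sim_config):
    """Shared toy mitogenome + plastome + truth ledger (expensive to build)."""
    from mitoscribe.simulate import make_organelles

    return make_organelles(sim_config)
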