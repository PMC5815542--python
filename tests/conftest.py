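import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cathcea import default_config  # noqa: E402


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def life_tables(cfg):
    return cfg.build_life_tables()


@pytest.fixture(scope="session")
def params(cfg):
    return cfg.model_parameters()


@pytest.fixture(scope="session")
def schedules(cfg):
    return cfg.cost_schedule(), cfg.utility_schedule()
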