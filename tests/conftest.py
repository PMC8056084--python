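import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down experiment: all structure, few plants, fast."""
    from basilight.synthetic_data import GradientConfig, SimulationConfig

    return SimulationConfig(seed=42, gradient=GradientConfig(n_positions=16))


@pytest.fixture(scope="session")
def small_experiment(small_config):
    from basilight.synthetic_data import simulate_plants

    return simulate_plants(small_config)
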