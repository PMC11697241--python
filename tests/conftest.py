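import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    from spikerel.stimulus import generate_pink_noise

    return generate_pink_noise(seed=1, sampling_rate_hz=5_000.0)


@pytest.fixture(scope="session")
def protocol(template):
    from spikerel.stimulus import build_protocol

    return build_protocol(template, rheobase_pa=100.0)


@pytest.fixture(scope="session")
def small_population():
    """Two well-separated classes, 8 neurons each (session-cached)."""
    from spikerel.synthetic_data import EXCITATORY_LIKE, PV_LIKE, simulate_population

    return simulate_population([PV_LIKE, EXCITATORY_LIKE], 8, rng_seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
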