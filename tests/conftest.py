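import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capnea.synth import SimConfig, simulate_night

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_night():
    """One-hour simulated night with a known 20 events/h target."""
    cfg = SimConfig(duration=60.0, sleep_latency=10.0, morning_wake=5.0,
                    target_ahi=20.0, seed=7)
    return simulate_night(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
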