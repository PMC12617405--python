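import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_gliding_config():
    """A small movie with stationary, event-free filaments."""
    from actimetry.simulate import GlidingSimConfig

    return GlidingSimConfig(
        n_filaments=3,
        motile_fraction=0.0,
        wobble_rate_per_s=0.0,
        detach_rate_per_s=0.0,
        n_frames=10,
        image_shape=(96, 96),
        min_separation_um=1.5,
        seed=42,
    )
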