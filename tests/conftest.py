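import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def step_trace():
    """Noiseless closed-form trace: step to 40 pA relaxing to 10 pA, C=10 pF."""
    from nartools import PhotocurrentTrace

    rate = 10_000.0
    time = np.arange(0, 1.5, 1.0 / rate)
    current = np.zeros_like(time)
    light_on, light_off = 0.2, 1.2
    in_light = (time >= light_on) & (time <= light_off)
    t_rel = time[in_light] - light_on
    current[in_light] = 10.0 + 30.0 * np.exp(-t_rel / 0.05)
    return PhotocurrentTrace(
        time=time, current=current, capacitance=10.0,
        light_on=light_on, light_off=light_off,
    )
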