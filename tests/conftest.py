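import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pmfield as pf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params() -> pf.PlantParams:
    return pf.PlantParams()


@pytest.fixture
def scheme() -> pf.RecombinationScheme:
    return pf.RecombinationScheme()


@pytest.fixture
def dark_light_series(params):
    """20 s dark, 180 s at 500 umol, 3 s extra for a dark interval."""
    schedule = pf.LightSchedule(((0.0, 0.0), (20.0, 500.0)),
                                photoperiod_h=200.0 / 3600.0,
                                day_type="constant")
    return pf.simulate_pmf_dynamics(params, schedule, dt=0.01, t_end=203.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
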