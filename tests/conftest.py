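import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from flucgrowth import (SteadyStateMap, make_shift_kernels,
                        length_from_volume)

settings.register_profile(
    "suite", max_examples=25, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_map():
    return SteadyStateMap()


@pytest.fixture(scope="session")
def default_kernels():
    return make_shift_kernels()


@pytest.fixture(scope="session")
def linear_kernels():
    return make_shift_kernels(shape="linear")


def exponential_track(mu_per_h, n_frames=40, dt_s=117.0, v0=2.0,
                      width=1.0, track_id="t0", t0_s=0.0,
                      condition="c", replicate_day="day1"):
    """Noise-free exponentially growing track at a constant rate."""
    t = t0_s + np.arange(n_frames) * dt_s
    v = v0 * 2.0 ** (mu_per_h * (t - t[0]) / 3600.0)
    return pd.DataFrame({
        "track_id": track_id,
        "time_s": t,
        "length_um": length_from_volume(v, width),
        "width_um": width,
        "condition": condition,
        "replicate_day": replicate_day,
    })


@pytest.fixture
def make_exp_track():
    return exponential_track
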