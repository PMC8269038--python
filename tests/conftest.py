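import numpy as np
import pytest
from hypothesis import settings

from scpassay import SpheroidTrajectory, TreatmentArm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_trajectory(
    rel_volumes,
    times=None,
    v0=1e6,
    spheroid_id="s0",
    dose_gy=0.0,
    ht_temp_c=37.0,
    ht_duration_min=0.0,
):
    """Trajectory from volumes given as multiples of V0."""
    rel = np.asarray(rel_volumes, dtype=float)
    t = np.arange(len(rel), dtype=float) * 2.5 if times is None else np.asarray(times, float)
    return SpheroidTrajectory(
        spheroid_id=spheroid_id,
        arm=TreatmentArm(ht_temp_c=ht_temp_c, ht_duration_min=ht_duration_min, dose_gy=dose_gy),
        times_d=t,
        volumes_um3=rel * v0,
        v0_um3=v0,
    )


def exponential_trajectory(doubling_time_d, times, v0=1e6, **kw):
    """Noise-free exponential growth V(t) = V0 * 2^(t/Td)."""
    t = np.asarray(times, dtype=float)
    return make_trajectory(2.0 ** (t / doubling_time_d), times=t, v0=v0, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
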