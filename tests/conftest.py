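import numpy as np
import pytest

import ultrarhythm as ur


def make_record(L=15, n_days=10, seed=0, rate_dark=20.0, rate_light=1.0,
                dark_ur=(), light_ur=(), jitter=0.0, alpha_hours=None):
    """Simulated record helper with explicit parameters."""
    params = ur.SimParams(
        schedule=ur.LightSchedule(L=float(L)),
        n_days=n_days,
        base_rate_dark=rate_dark,
        base_rate_light=rate_light,
        ur_dark=tuple(dark_ur),
        ur_light=tuple(light_ur),
        cr_onset_jitter=jitter,
        alpha_hours=alpha_hours,
        seed=seed,
    )
    return ur.simulate_animal(params)


@pytest.fixture(scope="session")
def record_15L():
    """10-day 15 L record with a 2.5 h dark ultradian component."""
    rec, truth = make_record(
        L=15, seed=11, dark_ur=[ur.URComponent(2.5, 0.8)], jitter=0.25
    )
    return rec, truth


@pytest.fixture(scope="session")
def dark_series_15L(record_15L):
    rec, _ = record_15L
    return ur.phase_series(rec, ur.LightSchedule(L=15.0), "dark")


def gapped_dark_times(L=15, n_days=10, bin_h=0.1):
    """Bin times (hours) of the dark-phase sampling pattern, gaps included."""
    dark_h = 24.0 - L
    per_night = int(round(dark_h / bin_h))
    t = []
    for d in range(n_days):
        t.append(24.0 * d + bin_h * np.arange(per_night))
    return np.concatenate(t)
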