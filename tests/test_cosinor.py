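"""Cosinor fits, acrophase conventions and activity-duration estimation."""
import numpy as np
import pytest

import ultrarhythm as ur
from ultrarhythm.cosinor import cosinor_fit_fixed, estimate_alpha
from ultrarhythm.errors import UndefinedAlphaError, ValidationError
from ultrarhythm.parsing import PhaseSeries
from tests.conftest import gapped_dark_times, make_record


def _series_from(t_hours, counts, L=15.0):
    t0 = np.datetime64("2024-01-01T18:00:00")  # a lights-off
    t_abs = t0 + (np.asarray(t_hours) * 3600).round().astype("timedelta64[s]")
    sched = ur.LightSchedule(L=L)
    return PhaseSeries(
        phase="dark", t_abs=t_abs, counts=np.asarray(counts, int),
        t_phase=np.zeros(len(t_hours)), n_segments=1.0, source_schedule=sched,
    )


class TestFixedPeriod:
    def test_exact_noiseless_recovery(self):
        t = 0.1 * np.arange(900)
        y = 5 + 3 * np.cos(2 * np.pi * t / 3.0)
        fit = cosinor_fit_fixed((t, y), 3.0)
        assert fit.mesor == pytest.approx(5.0, abs=1e-8)
        assert fit.amplitude_abs == pytest.approx(3.0, abs=1e-8)
        assert fit.amplitude_rel == pytest.approx(60.0, abs=1e-6)
        assert fit.robustness == pytest.approx(100.0, abs=1e-8)
        assert fit.p_zero_amp == 0.0

    def test_constant_series_is_rhythmless_not_an_error(self):
        t = 0.1 * np.arange(100)
        fit = cosinor_fit_fixed((t, np.full(100, 5.0)), 3.0)
        assert fit.amplitude_abs == 0.0
        assert fit.robustness == 0.0
        assert fit.p_zero_amp == pytest.approx(1.0)
        assert not fit.significant

    def test_preconditions(self):
        t = 0.1 * np.arange(100)
        y = np.cos(t)
        with pytest.raises(ValidationError):
            cosinor_fit_fixed((t[:3], y[:3]), 1.0)
        with pytest.raises(ValidationError):
            cosinor_fit_fixed((t, y), -1.0)
        with pytest.raises(ValidationError):
            cosinor_fit_fixed((t, y), 20.0)  # tau exceeds span

    def test_robustness_equals_glm_r2_oracle(self):
        """100*R^2 from the fit matches a brute-force linear-model solve."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = np.sort(rng.uniform(0, 90, 300))
            tau = rng.uniform(0.5, 8)
            y = rng.normal(2, 1, 300) + rng.uniform(0, 3) * np.cos(2 * np.pi * t / tau)
            fit = cosinor_fit_fixed((t, y), tau)
            w = 2 * np.pi / tau
            X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            ssr = ((y - X @ beta) ** 2).sum()
            sst = ((y - y.mean()) ** 2).sum()
            assert abs(fit.robustness - 100 * (1 - ssr / sst)) < 1e-8

    def test_noisy_recovery_within_5pct(self):
        """Median mesor/amplitude error over seeds stays below 5%."""
        errs_m, errs_a = [], []
        t = gapped_dark_times(L=15, n_days=10)
        for seed in range(30):
            rng = np.random.default_rng(900 + seed)
            mu = 20 * (1 + 0.6 * np.cos(2 * np.pi * t / 3.0))
            y = rng.poisson(np.maximum(mu, 0)).astype(float)
            fit = cosinor_fit_fixed((t, y), 3.0)
            errs_m.append(abs(fit.mesor - 20) / 20)
            errs_a.append(abs(fit.amplitude_abs - 12) / 12)
        assert np.median(errs_m) < 0.05
        assert np.median(errs_a) < 0.05


class TestScan:
    def test_recovers_programmed_period(self):
        rec, _ = make_record(L=12, seed=21, dark_ur=[ur.URComponent(2.0, 0.8)],
                             jitter=0.25)
        series = ur.phase_series(rec, ur.LightSchedule(L=12.0), "dark")
        scan = ur.CosinorScan().fit(series)
        assert scan.tau_ == pytest.approx(2.0, abs=0.02 + 1e-9)
        assert scan.significant_

    def test_cr_scan_pure_24h(self):
        """A clean 24 h rhythm scanned over 22-26 h lands on 24.0."""
        t = 0.1 * np.arange(2400)
        rng = np.random.default_rng(2)
        y = rng.poisson(10 * (1 + 0.8 * np.cos(2 * np.pi * t / 24.0)))
        scan = ur.CosinorScan(period_range=(22.0, 26.0), step=0.05).fit((t, y.astype(float)))
        assert scan.tau_ == pytest.approx(24.0, abs=0.05 + 1e-9)

    def test_zero_variance_rejected(self):
        t = 0.1 * np.arange(300)
        with pytest.raises(Exception):
            ur.CosinorScan().fit((t, np.zeros(300)))


class TestAcrophase:
    def test_peak_at_reference_is_zero(self):
        t = 0.1 * np.arange(900)
        y = 10 + 4 * np.cos(2 * np.pi * t / 3.0)  # peak at t=0 = lights-off
        fit = cosinor_fit_fixed(_series_from(t, np.round(y)), 3.0)
        h, a = ur.acrophase_reference(fit, ur.LightSchedule(L=15.0), "dark")
        assert min(h, 3.0 - h) < 0.02
        assert min(a, 2 * np.pi - a) < 0.05

    def test_quarter_period_is_half_pi(self):
        t = 0.1 * np.arange(900)
        y = 100 + 40 * np.cos(2 * np.pi * (t - 0.75) / 3.0)  # peak tau/4 after start
        fit = cosinor_fit_fixed(_series_from(t, np.round(y)), 3.0)
        h, a = ur.acrophase_reference(fit, ur.LightSchedule(L=15.0), "dark")
        assert h == pytest.approx(0.75, abs=0.02)
        assert a == pytest.approx(np.pi / 2, abs=0.05)

    def test_series_offset_from_reference_event(self):
        # series starts 2 h after lights-off; peak at series start
        t = 0.1 * np.arange(900)
        y = 100 + 40 * np.cos(2 * np.pi * t / 3.0)
        t0 = np.datetime64("2024-01-01T20:00:00")
        series = PhaseSeries(
            phase="dark",
            t_abs=t0 + (t * 3600).round().astype("timedelta64[s]"),
            counts=np.round(y).astype(int), t_phase=np.zeros(900),
            n_segments=1.0, source_schedule=ur.LightSchedule(L=15.0),
        )
        fit = cosinor_fit_fixed(series, 3.0)
        h, _ = ur.acrophase_reference(fit, ur.LightSchedule(L=15.0), "dark")
        assert h == pytest.approx(2.0, abs=0.02)  # 2 h after lights-off (mod 3)

    def test_time_shift_equivariance(self):
        """Shifting the series by d shifts acro_hours by d (mod tau), only."""
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 90, 400))
        y = 10 + 4 * np.cos(2 * np.pi * (t - 1.1) / 3.0) + rng.normal(0, 1, 400)
        f0 = cosinor_fit_fixed((t, y), 3.0)
        for d in (0.5, 1.7, 2.9):
            fd = cosinor_fit_fixed((t + d, y), 3.0)
            assert fd.mesor == pytest.approx(f0.mesor, abs=1e-8)
            assert fd.amplitude_abs == pytest.approx(f0.amplitude_abs, abs=1e-8)
            assert fd.robustness == pytest.approx(f0.robustness, abs=1e-8)
            delta = (fd.acro_hours - f0.acro_hours) % 3.0
            assert min(abs(delta - d % 3.0), 3.0 - abs(delta - d % 3.0)) < 1e-6

    def test_zero_amplitude_has_no_acrophase(self):
        t = 0.1 * np.arange(100)
        fit = cosinor_fit_fixed((t, np.full(100, 5.0)), 3.0)
        h, a = ur.acrophase_reference(fit, ur.LightSchedule(L=15.0), "dark")
        assert np.isnan(h) and np.isnan(a)


class TestAlpha:
    def _square_record(self, high=20, active_h=9.0):
        t0 = np.datetime64("2024-01-01T18:00:00")
        t = t0 + np.arange(2400) * np.timedelta64(360, "s")
        since = (np.arange(2400) * 0.1) % 24.0
        counts = np.where(since < active_h, high, 0)
        return ur.ActivityRecord("sq", t, counts)

    def test_square_wave_exact(self):
        rec = self._square_record()
        est = estimate_alpha(rec, ur.LightSchedule(L=15.0))
        assert est.alpha_hours == pytest.approx(9.0)
        assert est.onset_clock == pytest.approx(18.0)

    def test_recovery_with_jitter(self):
        errs = []
        for seed in range(12):
            rec, truth = make_record(L=9, seed=300 + seed, jitter=0.25,
                                     alpha_hours=11.4, rate_dark=20)
            est = estimate_alpha(rec, ur.LightSchedule(L=9.0))
            errs.append(est.alpha_hours - truth.alpha_hours)
        assert abs(np.median(errs)) < 0.3

    def test_flat_record_undefined(self):
        t0 = np.datetime64("2024-01-01T18:00:00")
        t = t0 + np.arange(2400) * np.timedelta64(360, "s")
        rec = ur.ActivityRecord("z", t, np.zeros(2400, int))
        with pytest.raises(UndefinedAlphaError):
            estimate_alpha(rec, ur.LightSchedule(L=15.0))

    def test_needs_five_days(self):
        rec = self._square_record()
        short = ur.ActivityRecord("s", rec.t[:960], rec.counts[:960])
        with pytest.raises(ValidationError):
            estimate_alpha(short, ur.LightSchedule(L=15.0))
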