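"""Cosinor rhythmometry: single-component cosine fits over a period grid.

The model is y(t) = M + A*cos(2*pi*(t - t_a)/tau) + e, fitted by linear least
squares on {1, cos(2*pi*t/tau), sin(2*pi*t/tau)}. Reported quantities follow
the standard rhythmometric vocabulary:

* mesor M — rhythm-adjusted mean,
* amplitude A — peak-to-mesor distance, absolute (counts/bin) and relative
  (percent of mesor),
* robustness — percent of variance explained, 100*R^2,
* acrophase — time (hours, or angle in radians in [0, 2*pi)) of the waveform
  peak relative to a reference event (lights-off for dark-phase and circadian
  fits, lights-on for light-phase fits),
* zero-amplitude test — F test of the two rhythm regressors on (2, n-3) df.

The best-fitting period tau' is chosen by scanning a period grid and
maximizing robustness ("cosinor periodogram"); ties break toward shorter tau.
Gapped absolute timestamps enter the regressors directly — no imputation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateSeriesError, UndefinedAlphaError, ValidationError
from .parsing import PhaseSeries
from .periodogram import CR_RANGE, CR_STEP, UR_RANGE, UR_STEP, _as_time_value, period_grid
from .schedule import ActivityRecord, LightSchedule, clock_hours


@dataclass
class CosinorFit:
    """Result of one fixed-period cosinor fit."""

    tau: float
    mesor: float
    amplitude_abs: float
    amplitude_rel: float  # percent of mesor (nan when mesor <= 0)
    robustness: float  # percent variance explained, 100*R^2
    acro_hours: float  # first peak at/after t=0 of the fitted series, in [0, tau)
    acro_angle: float  # radians in [0, 2*pi)
    p_zero_amp: float
    n_bins: int
    significant: bool  # zero-amplitude test at the 0.05 level
    t0_abs: Optional[np.datetime64] = None  # absolute time of the series origin


def cosinor_fit_fixed(series, tau: float, y=None) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period ``tau`` (hours).

    A constant series is not an error: it fits with amplitude 0, robustness 0
    and p_zero_amp = 1 (no rhythm is detectable in a flat record).
    """
    t, yv = _as_time_value(series, y)
    n = t.size
    if n <= 3:
        raise ValidationError("cosinor fit needs more than 3 bins")
    if tau <= 0:
        raise ValidationError("tau must be positive")
    span = t.max() - t.min()
    if tau >= span:
        raise ValidationError(f"tau={tau} h not shorter than series span {span:.3g} h")

    w = 2.0 * np.pi / tau
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    ssr = float(resid @ resid)
    sst = float(((yv - yv.mean()) ** 2).sum())

    mesor, bc, bs = (float(b) for b in beta)
    amp = float(np.hypot(bc, bs))
    t0_abs = series.t_abs[0] if isinstance(series, PhaseSeries) else None

    if sst == 0.0:
        return CosinorFit(
            tau=float(tau), mesor=mesor, amplitude_abs=0.0,
            amplitude_rel=0.0 if mesor > 0 else float("nan"),
            robustness=0.0, acro_hours=float("nan"), acro_angle=float("nan"),
            p_zero_amp=1.0, n_bins=n, significant=False, t0_abs=t0_abs,
        )

    robustness = 100.0 * (1.0 - ssr / sst)
    if ssr == 0.0:
        p = 0.0
    else:
        f = ((sst - ssr) / 2.0) / (ssr / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))

    # fitted waveform peaks where w*(t - t_peak) = 0: t_peak = atan2(bs, bc)/w
    acro_hours = (np.arctan2(bs, bc) / w) % tau if amp > 0 else float("nan")
    acro_angle = (2.0 * np.pi * acro_hours / tau) if amp > 0 else float("nan")
    return CosinorFit(
        tau=float(tau),
        mesor=mesor,
        amplitude_abs=amp,
        amplitude_rel=100.0 * amp / mesor if mesor > 0 else float("nan"),
        robustness=robustness,
        acro_hours=float(acro_hours),
        acro_angle=float(acro_angle),
        p_zero_amp=p,
        n_bins=n,
        significant=p <= 0.05,
        t0_abs=t0_abs,
    )


class FixedPeriodCosinor(BaseEstimator):
    """Cosinor fit at one fixed period, sklearn-style.

    After ``fit``: ``mesor_``, ``amplitude_``, ``amplitude_rel_``,
    ``robustness_``, ``acro_hours_``, ``acro_angle_``, ``p_zero_amp_``.
    """

    def __init__(self, period: float = 24.0):
        self.period = period

    def fit(self, series, y=None) -> "FixedPeriodCosinor":
        f = cosinor_fit_fixed(series, self.period, y=y)
        self.fit_ = f
        self.mesor_ = f.mesor
        self.amplitude_ = f.amplitude_abs
        self.amplitude_rel_ = f.amplitude_rel
        self.robustness_ = f.robustness
        self.acro_hours_ = f.acro_hours
        self.acro_angle_ = f.acro_angle
        self.p_zero_amp_ = f.p_zero_amp
        return self

    def predict(self, t) -> np.ndarray:
        """Fitted waveform evaluated at times ``t`` (hours)."""
        f = self.fit_
        t = np.asarray(t, float)
        if np.isnan(f.acro_hours):
            return np.full_like(t, f.mesor)
        return f.mesor + f.amplitude_abs * np.cos(
            2.0 * np.pi * (t - f.acro_hours) / f.tau
        )


class CosinorScan(BaseEstimator):
    """Cosinor periodogram: scan a period grid, keep the best-fit period.

    The selection rule maximizes robustness (percent variance explained);
    ties break toward the shorter period. After ``fit``: ``tau_`` plus the
    same fitted attributes as :class:`FixedPeriodCosinor`, and
    ``robustness_profile_`` over ``periods_``.
    """

    def __init__(
        self,
        period_range: Tuple[float, float] = UR_RANGE,
        step: float = UR_STEP,
    ):
        self.period_range = period_range
        self.step = step

    def fit(self, series, y=None) -> "CosinorScan":
        t, yv = _as_time_value(series, y)
        if t.size <= 3:
            raise ValidationError("cosinor scan needs more than 3 bins")
        span = t.max() - t.min()
        grid = period_grid(self.period_range, self.step)
        grid = grid[grid < span]
        if grid.size == 0:
            raise ValidationError("no grid period shorter than the series span")

        sst = float(((yv - yv.mean()) ** 2).sum())
        if sst == 0.0:
            raise DegenerateSeriesError("zero-variance series: no rhythm definable")

        ones = np.ones(t.size)
        robustness = np.empty(grid.size)
        for i, tau in enumerate(grid):
            w = 2.0 * np.pi / tau
            X = np.column_stack([ones, np.cos(w * t), np.sin(w * t)])
            _, res, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
            ssr = float(res[0]) if res.size else float(
                ((yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]) ** 2).sum()
            )
            robustness[i] = 100.0 * (1.0 - ssr / sst)
        best = int(np.argmax(robustness))  # first max -> shorter tau on ties
        f = cosinor_fit_fixed(series, float(grid[best]), y=y)
        self.periods_ = grid
        self.robustness_profile_ = robustness
        self.fit_ = f
        self.tau_ = f.tau
        self.mesor_ = f.mesor
        self.amplitude_ = f.amplitude_abs
        self.amplitude_rel_ = f.amplitude_rel
        self.robustness_ = f.robustness
        self.acro_hours_ = f.acro_hours
        self.acro_angle_ = f.acro_angle
        self.p_zero_amp_ = f.p_zero_amp
        self.significant_ = f.significant
        return self


def cosinor_periodogram(
    series,
    period_range: Tuple[float, float] = UR_RANGE,
    step: float = UR_STEP,
    y=None,
) -> CosinorFit:
    """Best-fit cosinor over a period grid (thin wrapper over CosinorScan)."""
    return CosinorScan(period_range, step).fit(series, y=y).fit_


def acrophase_reference(
    fit: CosinorFit, schedule: LightSchedule, phase: str
) -> Tuple[float, float]:
    """Acrophase re-expressed relative to the schedule's reference event.

    Dark-phase and circadian fits are referenced to lights-off, light-phase
    fits to lights-on: the returned ``acro_hours`` is the time in [0, tau) of
    the first fitted peak at/after the reference event, and ``acro_angle`` the
    corresponding angle in [0, 2*pi). Requires the fit to carry its absolute
    series origin. Amplitude 0 has no acrophase: returns (nan, nan).
    """
    if np.isnan(fit.acro_hours):
        return float("nan"), float("nan")
    if phase not in ("dark", "light", "cr"):
        raise ValidationError(f"phase must be dark/light/cr, got {phase!r}")
    ref_clock = schedule.lights_off if phase in ("dark", "cr") else schedule.lights_on
    if fit.t0_abs is None:
        offset = 0.0
    else:
        start_clock = float(clock_hours(np.array([fit.t0_abs], "datetime64[s]"))[0])
        offset = (start_clock - ref_clock) % 24.0
    acro_hours = (fit.acro_hours + offset) % fit.tau
    return acro_hours, 2.0 * np.pi * acro_hours / fit.tau


@dataclass
class AlphaEstimate:
    """Nocturnal activity duration and the onset/offset clock times (hours)."""

    alpha_hours: float
    onset_clock: float
    offset_clock: float
    profile: np.ndarray
    threshold: float


def estimate_alpha(
    record: ActivityRecord,
    schedule: LightSchedule,
    smooth_bins: int = 5,
    threshold: str = "midrange",
) -> AlphaEstimate:
    """Duration of the daily active phase from the folded activity profile.

    All days are folded into a mean daily profile on the record's bin grid,
    smoothed with a centered circular moving average (default 5 bins = 30 min
    at 6-min binning), and thresholded; alpha is the longest contiguous
    supra-threshold run (wrap-around allowed). ``threshold`` is ``"midrange"``
    (halfway between profile min and max, the default) or ``"mean"``.
    """
    bins_per_day = record.bins_per_day
    if len(record) < 5 * bins_per_day:
        raise ValidationError("alpha estimation needs at least 5 complete days")
    idx = np.round(
        clock_hours(record.t) * 60.0 / record.bin_minutes
    ).astype(int) % bins_per_day
    profile = np.bincount(idx, weights=record.counts.astype(float), minlength=bins_per_day)
    profile /= np.maximum(np.bincount(idx, minlength=bins_per_day), 1)

    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        ext = np.concatenate([profile[-(smooth_bins // 2):], profile, profile[: smooth_bins // 2]])
        profile = np.convolve(ext, kernel, mode="valid")

    lo, hi = float(profile.min()), float(profile.max())
    if hi == lo:
        raise UndefinedAlphaError("flat daily profile: activity duration undefined")
    thr = (lo + hi) / 2.0 if threshold == "midrange" else float(profile.mean())

    above = profile >= thr
    # longest run with wrap-around: scan the doubled mask, cap at one day
    doubled = np.concatenate([above, above])
    best_len, best_start, run, start = 0, 0, 0, 0
    for i, a in enumerate(doubled):
        if a:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
    best_len = min(best_len, bins_per_day)
    bin_h = record.bin_minutes / 60.0
    onset = (best_start % bins_per_day) * bin_h
    return AlphaEstimate(
        alpha_hours=best_len * bin_h,
        onset_clock=onset,
        offset_clock=(onset + best_len * bin_h) % 24.0,
        profile=profile,
        threshold=thr,
    )
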