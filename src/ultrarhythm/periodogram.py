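"""Lomb-Scargle periodogram for gapped, single-photophase activity series.

Implements the classic variance-normalized Lomb power

    P(w) = 1/(2 s^2) * { [sum (y-ybar) cos w(t-tau0)]^2 / sum cos^2 w(t-tau0)
                       + [sum (y-ybar) sin w(t-tau0)]^2 / sum sin^2 w(t-tau0) }

with tan(2 w tau0) = sum sin 2wt / sum cos 2wt and s^2 the (ddof=1) sample
variance. Under Gaussian white noise each P is exponentially distributed, so
with M independent frequencies the false-alarm level z for a family-wise rate
alpha is z = -ln(1 - (1-alpha)^(1/M)).

Significant-peak detection collapses each contiguous run of supra-threshold
grid points to a single peak at the run maximum; *complexity* is the number of
such peaks in the ultradian band (default 0.1-7.9 h) and *presence* is whether
any power reaches the threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateSeriesError, ValidationError
from .parsing import PhaseSeries

#: ultradian period band (hours) and grid step used throughout the analysis
UR_RANGE = (0.1, 7.9)
UR_STEP = 0.02
#: circadian band
CR_RANGE = (22.0, 26.0)
CR_STEP = 0.05


def period_grid(period_range: Tuple[float, float], step: float) -> np.ndarray:
    lo, hi = period_range
    if lo <= 0 or hi <= lo or step <= 0:
        raise ValidationError(f"invalid period grid {period_range} step {step}")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _as_time_value(series, y=None) -> Tuple[np.ndarray, np.ndarray]:
    if y is None:
        if isinstance(series, PhaseSeries):
            return np.asarray(series.t_hours, float), series.counts.astype(float)
        t, y = series
        return np.asarray(t, float), np.asarray(y, float)
    return np.asarray(series, float), np.asarray(y, float)


def lsp_power(series, periods, y=None) -> np.ndarray:
    """Classic normalized Lomb power at each grid period.

    ``series`` may be a :class:`PhaseSeries` or an array of times in hours
    (then ``y`` holds the values). Invariant to adding a constant to all
    values and to shifting all timestamps.
    """
    t, yv = _as_time_value(series, y)
    if t.size < 4:
        raise ValidationError("need at least 4 bins for a periodogram")
    yc = yv - yv.mean()
    ss = float(yc @ yc)
    if ss == 0.0:
        raise DegenerateSeriesError("zero-variance series: no rhythm definable")
    var = ss / (t.size - 1)

    periods = np.asarray(periods, float)
    if np.any(periods <= 0):
        raise ValidationError("grid periods must be positive")
    omega = 2.0 * np.pi / periods[:, None]  # (M, 1)
    wt = omega * t[None, :]  # (M, N)
    tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1)) / (
        2.0 * omega[:, 0]
    )
    arg = wt - omega * tau[:, None]
    c, s = np.cos(arg), np.sin(arg)
    pc = (c @ yc) ** 2 / (c * c).sum(axis=1)
    ps = (s @ yc) ** 2 / (s * s).sum(axis=1)
    return (pc + ps) / (2.0 * var)


def significance_threshold(M_indep: int, alpha: float = 0.01) -> float:
    """Power cutoff z with family-wise false-alarm probability ``alpha``.

    Inverts p = 1 - (1 - e^(-z))^M; monotone increasing in M, decreasing in
    alpha. M=1 reduces to z = -ln(alpha).
    """
    if M_indep < 1:
        raise ValidationError("M_indep must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    # log1p/expm1 keep precision for small alpha and large M
    return float(-np.log(-np.expm1(np.log1p(-alpha) / M_indep)))


def detect_peaks(
    periods: np.ndarray, power: np.ndarray, z_threshold: float
) -> Tuple[List[Tuple[float, float]], int, bool]:
    """Significant peaks above ``z_threshold``.

    Contiguous supra-threshold runs collapse to one (period, power) peak at
    the run maximum; two peaks must be separated by at least one sub-threshold
    grid point. Returns (peaks, complexity, presence).
    """
    periods = np.asarray(periods, float)
    power = np.asarray(power, float)
    above = power >= z_threshold
    peaks: List[Tuple[float, float]] = []
    i = 0
    n = len(power)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            k = i + int(np.argmax(power[i : j + 1]))
            peaks.append((float(periods[k]), float(power[k])))
            i = j + 1
        else:
            i += 1
    return peaks, len(peaks), bool(above.any())


@dataclass
class PeriodogramResult:
    """LSP power over a period grid plus the significance bookkeeping."""

    period_grid: np.ndarray
    power: np.ndarray
    alpha_level: float
    M_indep: int
    z_threshold: float
    peaks: List[Tuple[float, float]]
    complexity: int
    presence: bool
    dominant_period: float


class LombScarglePeriodogram(BaseEstimator):
    """Lomb-Scargle spectral estimator over a fixed period band.

    Parameters
    ----------
    period_range : (float, float)
        Period band in hours (default the ultradian band 0.1-7.9 h).
    step : float
        Grid step in hours.
    alpha : float
        Family-wise false-alarm level for the presence/complexity rule
        (the study convention is 0.01).
    m_indep : int or None
        Number of independent frequencies for the threshold. ``None`` uses
        the grid size (conservative).

    Attributes (after ``fit``)
    --------------------------
    periods_, power_ : the grid and normalized power
    z_threshold_ : significance cutoff
    peaks_ : list of (period, power) significant peaks
    complexity_ : number of significant peaks
    presence_ : whether any power reaches the threshold
    dominant_period_ : period of the global power maximum
    """

    def __init__(
        self,
        period_range: Tuple[float, float] = UR_RANGE,
        step: float = UR_STEP,
        alpha: float = 0.01,
        m_indep: Optional[int] = None,
    ):
        self.period_range = period_range
        self.step = step
        self.alpha = alpha
        self.m_indep = m_indep

    def fit(self, series, y=None) -> "LombScarglePeriodogram":
        """Compute the periodogram of a :class:`PhaseSeries` (or times, values)."""
        grid = period_grid(self.period_range, self.step)
        power = lsp_power(series, grid, y=y)
        m = len(grid) if self.m_indep is None else int(self.m_indep)
        z = significance_threshold(m, self.alpha)
        peaks, complexity, presence = detect_peaks(grid, power, z)
        self.periods_ = grid
        self.power_ = power
        self.M_indep_ = m
        self.z_threshold_ = z
        self.peaks_ = peaks
        self.complexity_ = complexity
        self.presence_ = presence
        self.dominant_period_ = float(grid[int(np.argmax(power))])
        return self

    def result_(self) -> PeriodogramResult:
        return PeriodogramResult(
            period_grid=self.periods_,
            power=self.power_,
            alpha_level=self.alpha,
            M_indep=self.M_indep_,
            z_threshold=self.z_threshold_,
            peaks=self.peaks_,
            complexity=self.complexity_,
            presence=self.presence_,
            dominant_period=self.dominant_period_,
        )


def lsp_analysis(
    series,
    period_range: Tuple[float, float] = UR_RANGE,
    step: float = UR_STEP,
    alpha: float = 0.01,
    m_indep: Optional[int] = None,
) -> PeriodogramResult:
    """One-call wrapper around :class:`LombScarglePeriodogram`."""
    return (
        LombScarglePeriodogram(period_range, step, alpha, m_indep).fit(series).result_()
    )
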