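"""Synthetic actogram generation with known circadian and ultradian structure.

Counts in each 6-min bin are independent Poisson draws with mean

    mu(t) = gate(t) * prod_k max(0, 1 + rel_amp_k * cos(2*pi*(t - phase0_k)/tau_k))

where the circadian gate is ``base_rate_dark`` inside the nightly active
window — a block of ``alpha_hours`` beginning at lights-off, with its onset
jittered day to day — and ``base_rate_light`` elsewhere. Ultradian components
are multiplicative rectified cosines in absolute time: ``ur_dark`` components
modulate the active window, ``ur_light`` components the light phase. Poisson
counts were chosen because passive-infrared detector bins hold small
nonnegative event counts; the day-to-day onset jitter keeps circadian
robustness away from the degenerate 100%.

Photoperiod presets encode the study's qualitative dose-response: shorter
days get a longer dark-phase ultradian period, larger relative amplitude,
a longer active phase and light-phase ultradian components; the short-day
nonresponder preset combines a long-day-like short active phase with the
longest dark-phase period.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .schedule import ActivityRecord, AnimalMetadata, LightSchedule

SIM_EPOCH = np.datetime64("2024-01-01T00:00:00", "s")


@dataclass(frozen=True)
class URComponent:
    """One multiplicative ultradian component: period (h), relative amplitude,
    and the absolute-time phase offset (h) of its first peak."""

    tau_u: float
    rel_amp: float
    phase0: float = 0.0

    def __post_init__(self):
        if not 0.1 <= self.tau_u <= 7.9:
            raise ValidationError(f"ultradian tau {self.tau_u} outside [0.1, 7.9] h")
        if self.rel_amp < 0:
            raise ValidationError("rel_amp must be >= 0")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one simulated animal."""

    schedule: LightSchedule
    n_days: int = 10
    base_rate_dark: float = 20.0
    base_rate_light: float = 1.0
    ur_dark: Tuple[URComponent, ...] = ()
    ur_light: Tuple[URComponent, ...] = ()
    cr_onset_jitter: float = 0.25
    alpha_hours: Optional[float] = None  # default: the full dark span
    seed: int = 0
    animal_id: str = "sim"
    bin_minutes: float = 6.0
    metadata: Optional[AnimalMetadata] = None

    def __post_init__(self):
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.base_rate_dark < 0 or self.base_rate_light < 0:
            raise ValidationError("rates must be >= 0")
        if self.alpha_hours is not None and not 0 < self.alpha_hours < 24:
            raise ValidationError("alpha_hours must lie in (0, 24)")
        if self.cr_onset_jitter < 0:
            raise ValidationError("cr_onset_jitter must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth stored alongside each simulated record."""

    params: SimParams
    day_onset_jitter: np.ndarray  # per-day active-window onset offset (h)
    alpha_hours: float
    dark_tau: Optional[float]  # programmed dominant dark-phase UR period
    light_tau: Optional[float]
    dark_rel_amp: float
    light_rel_amp: float
    phenotype: str = "responder"


def _modulation(t_h: np.ndarray, comps: Sequence[URComponent]) -> np.ndarray:
    mod = np.ones_like(t_h)
    for c in comps:
        mod *= np.maximum(
            0.0, 1.0 + c.rel_amp * np.cos(2.0 * np.pi * (t_h - c.phase0) / c.tau_u)
        )
    return mod


def simulate_animal(
    params: SimParams, phenotype: str = "responder"
) -> Tuple[ActivityRecord, TruthRecord]:
    """Simulate one animal's record; identical seed gives identical output.

    The record starts at the first lights-off, so hour 0 of the series is the
    dark-phase reference event.
    """
    sched = params.schedule
    rng = np.random.default_rng(params.seed)
    bin_h = params.bin_minutes / 60.0
    n_bins = int(round(params.n_days * 24.0 / bin_h))
    t_h = np.arange(n_bins) * bin_h  # hours since first lights-off

    start_day = SIM_EPOCH + np.timedelta64(int(round(sched.lights_off * 3600)), "s")
    t_abs = start_day + (t_h * 3600).round().astype("timedelta64[s]")

    alpha = sched.dark_hours if params.alpha_hours is None else params.alpha_hours
    jitter = rng.normal(0.0, params.cr_onset_jitter, size=params.n_days)

    # nightly active window [24 d + j_d, 24 d + j_d + alpha); a bin belongs to
    # the window iff its start falls inside (handles negative jitter cleanly)
    active = np.zeros(n_bins, dtype=bool)
    for d in range(params.n_days):
        lo = 24.0 * d + jitter[d]
        hi = lo + alpha
        active[np.searchsorted(t_h, lo, "left") : np.searchsorted(t_h, hi, "left")] = True
    in_light = (t_h % 24.0) >= sched.dark_hours  # record starts at lights-off
    active &= ~in_light  # light masking: light suppresses the active-window rate

    gate = np.where(active, params.base_rate_dark, params.base_rate_light)
    mod = np.ones(n_bins)
    if params.ur_dark:
        mod_dark = _modulation(t_h, params.ur_dark)
        mod = np.where(active, mod_dark, mod)
    if params.ur_light:
        mod_light = _modulation(t_h, params.ur_light)
        mod = np.where(in_light & ~active, mod_light, mod)
    mu = gate * mod
    if np.any(mu < 0):  # unreachable after rectification; guards the invariant
        raise ValidationError("negative Poisson rate after composition")
    counts = rng.poisson(mu)

    record = ActivityRecord(
        animal_id=params.animal_id,
        t=t_abs,
        counts=counts,
        bin_minutes=params.bin_minutes,
        metadata=params.metadata,
    )
    truth = TruthRecord(
        params=params,
        day_onset_jitter=jitter,
        alpha_hours=alpha,
        dark_tau=params.ur_dark[0].tau_u if params.ur_dark else None,
        light_tau=params.ur_light[0].tau_u if params.ur_light else None,
        dark_rel_amp=params.ur_dark[0].rel_amp if params.ur_dark else 0.0,
        light_rel_amp=params.ur_light[0].rel_amp if params.ur_light else 0.0,
        phenotype=phenotype,
    )
    return record, truth


# --- photoperiod presets -----------------------------------------------------

#: programmed dark-phase UR period (h) by photoperiod; nonresponders use 5.5 h.
#: short-day responder period 3.8 h is deliberately incommensurate with 24 h so
#: that folding days does not phase-lock the ultradian oscillation
DARK_TAU = {9: 3.8, 10: 3.8, 11: 3.8, 12: 3.8, 13: 3.8, 14: 2.5, 15: 2.5}
NONRESPONDER_DARK_TAU = 5.5
LIGHT_TAU = 1.3


def preset_alpha_hours(L: float) -> float:
    """Active-phase duration preset: 8.9 h at 15 L rising linearly to 11.4 h at 9 L."""
    return 8.9 + (15.0 - L) * (11.4 - 8.9) / 6.0


def preset_params(
    photoperiod_L: int,
    phenotype: str = "responder",
    n_days: int = 10,
    seed: int = 0,
    animal_id: str = "sim",
) -> SimParams:
    """Default generative preset for one photoperiod and reproductive phenotype.

    ``phenotype`` is ``"responder"`` (gonadally regressed in short days; the
    typical long-day animal at 14-15 L) or ``"nonresponder"`` (retains
    developed gonads: the SD-NR phenotype at <=12 L, the developed-testes
    variant at 13-14 L).
    """
    L = int(photoperiod_L)
    if L not in DARK_TAU:
        raise ValidationError(f"no preset for photoperiod {L} L")
    if phenotype not in ("responder", "nonresponder"):
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    sched = LightSchedule(L=float(L))
    short_day = L <= 13
    nr = phenotype == "nonresponder" and L <= 12

    if nr:
        dark = (URComponent(NONRESPONDER_DARK_TAU, 0.6),)
        light: Tuple[URComponent, ...] = ()
        alpha, jitter, rate = 8.9, 0.25, 20.0
    else:
        dark_amp = 0.8 if short_day else 0.6
        dark = (URComponent(DARK_TAU[L], dark_amp),)
        if L >= 15:
            light = ()
        elif L == 14:
            light = (URComponent(LIGHT_TAU, 0.2),)
        else:
            amp = 0.25 if (L == 13 and phenotype == "nonresponder") else 0.5
            light = (URComponent(LIGHT_TAU, amp),)
        alpha = preset_alpha_hours(L)
        jitter = 0.25 if L == 15 else 0.5
        rate = 20.0 if L == 15 else 16.0

    return SimParams(
        schedule=sched,
        n_days=n_days,
        base_rate_dark=rate,
        base_rate_light=1.0,
        ur_dark=dark,
        ur_light=light,
        cr_onset_jitter=jitter,
        alpha_hours=alpha,
        seed=seed,
        animal_id=animal_id,
    )


def _draw_metadata(
    L: int, phenotype: str, rng: np.random.Generator
) -> AnimalMetadata:
    developed = phenotype == "nonresponder" or L == 15
    if developed:
        etv = float(rng.uniform(320.0, 700.0))
        fur = 1
        mass = float(rng.normal(33.0, 1.5))
    else:
        etv = float(rng.uniform(40.0, 250.0))
        fur = int(rng.integers(3, 5)) if L <= 12 else int(rng.integers(1, 3))
        mass = float(rng.normal(28.0, 1.5))
    return AnimalMetadata(
        photoperiod_L=float(L), etv_week12=etv, fur_score=fur, body_mass=max(mass, 15.0)
    )


@dataclass(frozen=True)
class GroupDesign:
    photoperiod_L: int
    n_responder: int = 0
    n_nonresponder: int = 0


def study_design() -> List[GroupDesign]:
    """Group sizes of the combined study (main cohort plus the concurrent one),
    with the reported nonresponder counts in 10-12 L and the developed-testes
    counts at 13-14 L."""
    return [
        GroupDesign(9, 20, 0),
        GroupDesign(10, 20, 4),
        GroupDesign(11, 17, 6),
        GroupDesign(12, 18, 5),
        GroupDesign(13, 16, 8),
        GroupDesign(14, 5, 18),
        GroupDesign(15, 19, 0),
    ]


def simulate_cohort(
    design: Sequence[GroupDesign],
    n_days: int = 10,
    seed: int = 0,
) -> List[Tuple[ActivityRecord, TruthRecord]]:
    """Simulate one record per animal across photoperiod groups.

    Per-animal RNG streams are spawned from ``seed``, so the cohort is fully
    reproducible and insensitive to group ordering conventions downstream.
    """
    design = list(design)
    if not design or all(g.n_responder + g.n_nonresponder == 0 for g in design):
        raise ValidationError("empty cohort design")
    ss = np.random.SeedSequence(seed)
    out: List[Tuple[ActivityRecord, TruthRecord]] = []
    idx = 0
    for g in design:
        for phenotype, n in (("responder", g.n_responder), ("nonresponder", g.n_nonresponder)):
            for _ in range(n):
                child = ss.spawn(1)[0]
                animal_seed = int(child.generate_state(1)[0] % (2**31))
                meta_rng = np.random.default_rng(animal_seed + 1)
                params = replace(
                    preset_params(
                        g.photoperiod_L,
                        phenotype,
                        n_days=n_days,
                        seed=animal_seed,
                        animal_id=f"a{idx:03d}_L{g.photoperiod_L}_{phenotype[:4]}",
                    ),
                    metadata=_draw_metadata(g.photoperiod_L, phenotype, meta_rng),
                )
                out.append(simulate_animal(params, phenotype=phenotype))
                idx += 1
    return out
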