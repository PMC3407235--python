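"""Per-animal and cohort orchestration of the full analysis.

For each animal: split the record into photophases, build 900-bin equalized
dark and light series, run the Lomb-Scargle presence/complexity rule per
phase (family-wise alpha 0.01), quantify each present rhythm with the cosinor
periodogram (zero-amplitude alpha 0.05), fit the circadian waveform on the
unparsed contiguous record over 22-26 h, and estimate the nightly activity
duration. Ultradian quantification is gated on spectral presence: a phase
with no significant periodogram peak contributes no cosinor fit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cosinor import (
    AlphaEstimate,
    CosinorFit,
    CosinorScan,
    acrophase_reference,
    estimate_alpha,
)
from .errors import ShortfallError, UltrarhythmError, ValidationError
from .parsing import PhaseSeries, phase_series, split_phases
from .periodogram import (
    CR_RANGE,
    CR_STEP,
    UR_RANGE,
    UR_STEP,
    LombScarglePeriodogram,
    PeriodogramResult,
)
from .schedule import ActivityRecord, LightSchedule
from .stats import classify_phenotype, polynomial_contrasts, prevalence_chi2, regress


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed analysis constants; defaults follow the study conventions."""

    ur_range: Tuple[float, float] = UR_RANGE
    cr_range: Tuple[float, float] = CR_RANGE
    ur_step: float = UR_STEP
    cr_step: float = CR_STEP
    alpha_lsp: float = 0.01
    alpha_cosinor: float = 0.05
    target_points: int = 900
    cr_days: int = 10
    alpha_threshold: str = "midrange"  # activity-duration threshold rule
    alpha_smooth_bins: int = 5
    m_indep: Optional[int] = None  # None -> grid size (conservative)

    def __post_init__(self):
        for lo, hi in (self.ur_range, self.cr_range):
            if not 0 < lo < hi:
                raise ValidationError("period ranges must be positive and ordered")
        for a in (self.alpha_lsp, self.alpha_cosinor):
            if not 0.0 < a < 1.0:
                raise ValidationError("significance levels must lie in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PhaseAnalysis:
    """LSP + (presence-gated) cosinor quantification for one photophase."""

    phase: str
    periodogram: PeriodogramResult
    presence: bool
    complexity: int
    fit: Optional[CosinorFit]  # None when the LSP finds no rhythm
    acro_hours: float = float("nan")
    acro_angle: float = float("nan")


@dataclass
class RhythmSummary:
    """Per-animal bundle: dark/light ultradian, circadian, activity duration."""

    animal_id: str
    dark_ur: PhaseAnalysis
    light_ur: PhaseAnalysis
    cr: PhaseAnalysis
    alpha: AlphaEstimate
    phenotype: Optional[str] = None


def _analyze_phase(
    series, phase: str, schedule: LightSchedule, config: AnalysisConfig,
    period_range, step,
) -> PhaseAnalysis:
    lsp = LombScarglePeriodogram(
        period_range=period_range, step=step,
        alpha=config.alpha_lsp, m_indep=config.m_indep,
    ).fit(series)
    fit = None
    acro_h = acro_a = float("nan")
    if lsp.presence_:
        scan = CosinorScan(period_range=period_range, step=step).fit(series)
        fit = scan.fit_
        ref_phase = "cr" if phase == "cr" else phase
        acro_h, acro_a = acrophase_reference(fit, schedule, ref_phase)
    return PhaseAnalysis(
        phase=phase,
        periodogram=lsp.result_(),
        presence=lsp.presence_,
        complexity=lsp.complexity_,
        fit=fit,
        acro_hours=acro_h,
        acro_angle=acro_a,
    )


def analyze_animal(
    record: ActivityRecord,
    schedule: LightSchedule,
    config: AnalysisConfig = AnalysisConfig(),
) -> RhythmSummary:
    """Run the full deterministic per-animal analysis.

    Raises :class:`ShortfallError` (naming the phase) when a photophase cannot
    supply the equalized series, and propagates stage errors unchanged.
    """
    try:
        dark = phase_series(record, schedule, "dark", config.target_points)
    except ShortfallError as exc:
        raise ShortfallError(exc.available, exc.required, "dark-phase bins") from exc
    try:
        light = phase_series(record, schedule, "light", config.target_points)
    except ShortfallError as exc:
        raise ShortfallError(exc.available, exc.required, "light-phase bins") from exc

    dark_an = _analyze_phase(dark, "dark", schedule, config, config.ur_range, config.ur_step)
    light_an = _analyze_phase(light, "light", schedule, config, config.ur_range, config.ur_step)

    # circadian fit uses the unparsed contiguous file (240 bins/day, 10 days)
    cr_bins = config.cr_days * record.bins_per_day
    if len(record) < cr_bins:
        raise ShortfallError(len(record), cr_bins, "unparsed bins")
    cr_record = ActivityRecord(
        animal_id=record.animal_id,
        t=record.t[:cr_bins],
        counts=record.counts[:cr_bins],
        bin_minutes=record.bin_minutes,
        metadata=record.metadata,
    )
    cr_series = PhaseSeries(
        phase="all",
        t_abs=cr_record.t,
        counts=cr_record.counts,
        t_phase=schedule.hours_since_phase_onset(cr_record.t),
        n_segments=float(config.cr_days),
        source_schedule=schedule,
        bin_minutes=record.bin_minutes,
    )
    cr_an = _analyze_phase(cr_series, "cr", schedule, config, config.cr_range, config.cr_step)

    alpha = estimate_alpha(
        cr_record, schedule,
        smooth_bins=config.alpha_smooth_bins, threshold=config.alpha_threshold,
    )
    phenotype = classify_phenotype(record.metadata) if record.metadata else None
    return RhythmSummary(
        animal_id=record.animal_id,
        dark_ur=dark_an,
        light_ur=light_an,
        cr=cr_an,
        alpha=alpha,
        phenotype=phenotype,
    )


def summary_row(s: RhythmSummary, meta=None) -> Dict[str, float]:
    """Flatten a RhythmSummary into one cohort-table row."""
    row: Dict[str, object] = {"animal_id": s.animal_id, "phenotype": s.phenotype}
    if meta is not None:
        row.update(
            photoperiod_L=meta.photoperiod_L, etv=meta.etv_week12,
            fur_score=meta.fur_score, mass=meta.body_mass,
        )
    for name, an in (("dark", s.dark_ur), ("light", s.light_ur), ("cr", s.cr)):
        row[f"{name}_presence"] = an.presence
        row[f"{name}_complexity"] = an.complexity
        if an.fit is not None:
            row[f"{name}_tau"] = an.fit.tau
            row[f"{name}_mesor"] = an.fit.mesor
            row[f"{name}_amplitude"] = an.fit.amplitude_abs
            row[f"{name}_amplitude_rel"] = an.fit.amplitude_rel
            row[f"{name}_robustness"] = an.fit.robustness
            row[f"{name}_acro_hours"] = an.acro_hours
            row[f"{name}_acro_angle"] = an.acro_angle
        else:
            for k in ("tau", "mesor", "amplitude", "amplitude_rel",
                      "robustness", "acro_hours", "acro_angle"):
                row[f"{name}_{k}"] = float("nan")
    row["alpha_hours"] = s.alpha.alpha_hours
    return row


@dataclass
class CohortReport:
    """Cohort-level outputs: per-animal table plus group aggregates."""

    animals: pd.DataFrame
    group_means: pd.DataFrame
    prevalence: pd.DataFrame
    config: AnalysisConfig

    def save(self, out_dir) -> Path:
        out = Path(out_dir) / f"report_{self.config.hash()}"
        out.mkdir(parents=True, exist_ok=True)
        self.animals.to_csv(out / "animals.csv", index=False)
        self.group_means.to_csv(out / "group_means.csv")
        self.prevalence.to_csv(out / "prevalence.csv")
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), default=str, indent=1)
        )
        return out


ENDPOINTS = [
    "dark_complexity", "dark_tau", "dark_robustness", "dark_mesor",
    "dark_amplitude", "dark_amplitude_rel", "dark_acro_hours",
    "light_complexity", "light_tau", "light_robustness", "light_mesor",
    "light_amplitude", "light_amplitude_rel", "light_acro_hours",
    "cr_tau", "cr_robustness", "cr_mesor", "cr_amplitude_rel",
    "cr_acro_angle", "alpha_hours",
]


def run_cohort(
    animals: Sequence[Tuple[ActivityRecord, LightSchedule]],
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortReport:
    """Analyze every animal and aggregate group tables.

    ``animals`` is a sequence of (record, schedule) pairs; records carry
    their metadata. Deterministic: rerunning with the same inputs and config
    reproduces the report exactly.
    """
    rows = []
    for record, schedule in animals:
        s = analyze_animal(record, schedule, config)
        rows.append(summary_row(s, record.metadata))
    df = pd.DataFrame(rows)

    by = df.groupby("photoperiod_L") if "photoperiod_L" in df else df.groupby("phenotype")
    cols = [c for c in ENDPOINTS if c in df.columns]
    means = by[cols].mean()
    sems = by[cols].sem()
    group_means = pd.concat({"mean": means, "sem": sems}, axis=1)

    prev = by[["dark_presence", "light_presence", "cr_presence"]].mean() * 100.0
    prev.columns = [c.replace("presence", "prevalence_pct") for c in prev.columns]
    counts = by["animal_id"].count().rename("n")
    prevalence = pd.concat([counts, prev], axis=1)

    return CohortReport(animals=df, group_means=group_means,
                        prevalence=prevalence, config=config)
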