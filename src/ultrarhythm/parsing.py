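"""Photophase parsing: split records into dark/light blocks and build
concatenated, length-equalized analysis series.

A record is split into per-day phase blocks (dark blocks run lights-off to
lights-on, light blocks the reverse). Blocks are then concatenated
earliest-first and truncated to a fixed number of bins (default 900) so that
series lengths are comparable across photoperiods: at 15 L the dark file uses
10 full nights of 90 bins, at 12 L it uses 7.5 nights of 120 bins.

Absolute timestamps are retained across the inter-night gaps by default; the
spectral machinery downstream handles the uneven sampling. A contiguous
re-indexing is available behind ``reindex=True`` for sensitivity analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ShortfallError, ValidationError
from .schedule import ActivityRecord, LightSchedule

_HOUR = np.timedelta64(3600, "s")


@dataclass
class PhaseSegment:
    """One contiguous block of same-phase bins (one night or one day)."""

    phase: str  # "dark" | "light"
    t: np.ndarray  # bin-start timestamps, datetime64[s]
    counts: np.ndarray
    t_phase: np.ndarray  # hours since this block's phase onset
    complete: bool

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class PhaseSeries:
    """Concatenated single-photophase series (gapped absolute timestamps)."""

    phase: str
    t_abs: np.ndarray
    counts: np.ndarray
    t_phase: np.ndarray
    n_segments: float
    source_schedule: LightSchedule
    bin_minutes: float = 6.0
    reindexed: bool = False

    def __post_init__(self):
        if self.t_abs.size != self.counts.size:
            raise ValidationError("timestamps and counts differ in length")
        if self.t_abs.size > 1 and not np.all(np.diff(self.t_abs) > np.timedelta64(0, "s")):
            raise ValidationError("phase series timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t_abs.size)

    @property
    def t_hours(self) -> np.ndarray:
        """Analysis time axis in hours.

        Hours since the first retained bin (gaps preserved), or a contiguous
        bin-index axis when the series was re-indexed.
        """
        if self.reindexed:
            return np.arange(len(self)) * self.bin_minutes / 60.0
        return (self.t_abs - self.t_abs[0]) / _HOUR


def split_phases(
    record: ActivityRecord, schedule: LightSchedule
) -> Tuple[List[PhaseSegment], List[PhaseSegment]]:
    """Split a record into dark-only and light-only contiguous blocks.

    Every bin is assigned to exactly one phase by its start time. Returns
    ``(dark_segments, light_segments)`` in chronological order. A record
    shorter than one full phase block yields a partial segment and a warning.
    """
    dark_mask = schedule.in_dark(record.t)
    t_phase_all = schedule.hours_since_phase_onset(record.t)
    bin_h = record.bin_minutes / 60.0

    # block id increments at every phase flip or temporal discontinuity
    flip = np.empty(len(record), dtype=bool)
    flip[0] = True
    if len(record) > 1:
        step = np.timedelta64(int(round(record.bin_minutes * 60)), "s")
        flip[1:] = (dark_mask[1:] != dark_mask[:-1]) | (np.diff(record.t) != step)
    block_id = np.cumsum(flip)

    dark_segments: List[PhaseSegment] = []
    light_segments: List[PhaseSegment] = []
    for bid in np.unique(block_id):
        sel = block_id == bid
        phase = "dark" if dark_mask[np.argmax(sel)] else "light"
        duration = schedule.dark_hours if phase == "dark" else schedule.L
        expected = int(round(duration / bin_h))
        seg = PhaseSegment(
            phase=phase,
            t=record.t[sel],
            counts=record.counts[sel],
            t_phase=t_phase_all[sel],
            complete=int(sel.sum()) == expected,
        )
        (dark_segments if phase == "dark" else light_segments).append(seg)

    if not any(s.complete for s in dark_segments + light_segments):
        warnings.warn(
            "record shorter than one full phase block; partial segments returned",
            stacklevel=2,
        )
    return dark_segments, light_segments


def concatenate_equalized(
    segments: Sequence[PhaseSegment],
    target_points: int = 900,
    schedule: LightSchedule | None = None,
    bin_minutes: float = 6.0,
    drop_partial_leading: bool = True,
    reindex: bool = False,
) -> PhaseSeries:
    """Concatenate phase blocks earliest-first and truncate to ``target_points``.

    The final block used is cut at its end so the series has exactly the
    target length; ``n_segments`` reports the (possibly fractional) number of
    phase blocks consumed, e.g. 900 bins from 110-bin nights at 13 L uses
    8 + 20/110 ~= 8.18 nights. Raises :class:`ShortfallError` naming available
    vs required bins when the data cannot supply the target.
    """
    if target_points < 1:
        raise ValidationError("target_points must be >= 1")
    segs = list(segments)
    if not segs:
        raise ShortfallError(0, target_points)
    phase = segs[0].phase
    if any(s.phase != phase for s in segs):
        raise ValidationError("segments mix phases")
    if drop_partial_leading and len(segs) > 1 and not segs[0].complete:
        segs = segs[1:]

    available = sum(len(s) for s in segs)
    if available < target_points:
        raise ShortfallError(available, target_points)

    used_t, used_counts, used_tphase = [], [], []
    n_segments = 0.0
    remaining = target_points
    for seg in segs:
        take = min(len(seg), remaining)
        used_t.append(seg.t[:take])
        used_counts.append(seg.counts[:take])
        used_tphase.append(seg.t_phase[:take])
        n_segments += take / len(seg)
        remaining -= take
        if remaining == 0:
            break

    sched = schedule if schedule is not None else LightSchedule(L=12.0)
    return PhaseSeries(
        phase=phase,
        t_abs=np.concatenate(used_t),
        counts=np.concatenate(used_counts),
        t_phase=np.concatenate(used_tphase),
        n_segments=n_segments,
        source_schedule=sched,
        bin_minutes=bin_minutes,
        reindexed=reindex,
    )


def phase_series(
    record: ActivityRecord,
    schedule: LightSchedule,
    phase: str,
    target_points: int = 900,
    reindex: bool = False,
) -> PhaseSeries:
    """Convenience: split a record and build the equalized series for one phase."""
    if phase not in ("dark", "light"):
        raise ValidationError(f"phase must be 'dark' or 'light', got {phase!r}")
    dark, light = split_phases(record, schedule)
    segs = dark if phase == "dark" else light
    return concatenate_equalized(
        segs,
        target_points=target_points,
        schedule=schedule,
        bin_minutes=record.bin_minutes,
        reindex=reindex,
    )
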