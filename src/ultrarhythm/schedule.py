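"""Data model: light schedules, animal metadata and binned activity records.

Timestamps are naive local clock time (the colony light cycle is the clock;
no DST adjustment) stored as ``numpy.datetime64``. A record's timestamps mark
bin *starts*; bins are half-open ``[t, t + bin_width)`` and a bin belongs to
the dark phase iff its start lies inside the dark span.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidPhotoperiodError, ValidationError

#: default acquisition bin width used throughout the study design
DEFAULT_BIN_MINUTES = 6.0

_HOUR = np.timedelta64(3600, "s")


def parse_clock(value) -> float:
    """Parse a clock time ('18:00', '18:30:00' or a float hour) to hours in [0, 24)."""
    if isinstance(value, str):
        parts = value.split(":")
        if not 1 <= len(parts) <= 3 or not all(p.strip() for p in parts):
            raise ValidationError(f"cannot parse clock time {value!r}")
        h = float(parts[0])
        m = float(parts[1]) if len(parts) > 1 else 0.0
        s = float(parts[2]) if len(parts) > 2 else 0.0
        hour = h + m / 60.0 + s / 3600.0
    else:
        hour = float(value)
    if not 0.0 <= hour < 24.0:
        raise ValidationError(f"clock time {value!r} outside [0, 24) hours")
    return hour


def clock_hours(t: np.ndarray) -> np.ndarray:
    """Hours since local midnight for each timestamp (vectorized)."""
    t = np.asarray(t, dtype="datetime64[s]")
    midnight = t.astype("datetime64[D]").astype("datetime64[s]")
    return (t - midnight) / _HOUR


@dataclass(frozen=True)
class LightSchedule:
    """Daily light:dark schedule with a fixed lights-off clock time.

    Parameters
    ----------
    L : float
        Hours of light per day, in the open interval (0, 24). The study
        photoperiods are written ``L`` h light/day (e.g. ``15 L``).
    lights_off : float
        Clock time of dark onset in hours (default 18.0, i.e. 18:00).
    """

    L: float
    lights_off: float = 18.0

    def __post_init__(self):
        if not 0.0 < self.L < 24.0:
            raise InvalidPhotoperiodError(
                f"photoperiod L={self.L} must lie strictly between 0 and 24 h"
            )
        object.__setattr__(self, "lights_off", parse_clock(self.lights_off))

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.L

    @property
    def lights_on(self) -> float:
        """Clock time of light onset: lights_off + dark duration (mod 24)."""
        return (self.lights_off + self.dark_hours) % 24.0

    def in_dark(self, t) -> np.ndarray:
        """True where timestamps fall in the dark span (vectorized, 24 h periodic)."""
        h = clock_hours(np.atleast_1d(np.asarray(t, dtype="datetime64[s]")))
        since_off = (h - self.lights_off) % 24.0
        return since_off < self.dark_hours

    def in_light(self, t) -> np.ndarray:
        return ~self.in_dark(t)

    def hours_since_phase_onset(self, t) -> np.ndarray:
        """Per-timestamp hours since the current phase block began.

        For dark timestamps, hours since the preceding lights-off; for light
        timestamps, hours since the preceding lights-on.
        """
        h = clock_hours(np.atleast_1d(np.asarray(t, dtype="datetime64[s]")))
        since_off = (h - self.lights_off) % 24.0
        dark = since_off < self.dark_hours
        return np.where(dark, since_off, since_off - self.dark_hours)


def build_schedule(L: float, lights_off="18:00") -> LightSchedule:
    """Build a :class:`LightSchedule` from light hours and a lights-off clock time."""
    return LightSchedule(L=float(L), lights_off=parse_clock(lights_off))


@dataclass(frozen=True)
class AnimalMetadata:
    """Reproductive and somatic metadata for one animal.

    ``etv_week12`` is the estimated testis volume (testis length x width^2,
    arbitrary units); ``fur_score`` is the pelage score, 1 (agouti summer fur)
    to 4 (white winter fur); ``body_mass`` is grams.
    """

    photoperiod_L: float
    etv_week12: float
    fur_score: int
    body_mass: float

    def __post_init__(self):
        if self.fur_score not in (1, 2, 3, 4):
            raise ValidationError(f"fur_score {self.fur_score} not in {{1,2,3,4}}")
        if self.etv_week12 < 0:
            raise ValidationError("etv_week12 must be >= 0")
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be > 0")


@dataclass
class ActivityRecord:
    """Uniformly binned activity-count series for one animal.

    Invariants (validated at construction): timestamps strictly increasing and
    all separated by integer multiples of ``bin_width``; counts nonnegative
    integers; at least one bin.
    """

    animal_id: str
    t: np.ndarray
    counts: np.ndarray
    bin_minutes: float = DEFAULT_BIN_MINUTES
    metadata: Optional[AnimalMetadata] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype="datetime64[s]")
        counts = np.asarray(self.counts)
        if counts.size == 0 or self.t.size == 0:
            raise ValidationError("record must contain at least one bin")
        if counts.shape != self.t.shape:
            raise ValidationError("timestamps and counts differ in length")
        if np.any(counts < 0):
            raise ValidationError("counts must be nonnegative")
        if not np.all(counts == np.round(counts)):
            raise ValidationError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if self.t.size > 1:
            step = np.timedelta64(int(round(self.bin_minutes * 60)), "s")
            diffs = np.diff(self.t)
            if np.any(diffs <= np.timedelta64(0, "s")):
                raise ValidationError("timestamps must be strictly increasing")
            rem = (diffs / step) % 1.0
            if not np.allclose(rem, 0.0):
                raise ValidationError(
                    "timestamps must be separated by integer multiples of the bin width"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ActivityRecord):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.bin_minutes == other.bin_minutes
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.counts, other.counts)
            and self.metadata == other.metadata
        )

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_minutes))

    @property
    def n_days(self) -> float:
        """Record span in days, counting the final bin's width."""
        span = (self.t[-1] - self.t[0]) / _HOUR + self.bin_minutes / 60.0
        return float(span) / 24.0

    def t_hours(self, origin=None) -> np.ndarray:
        """Bin-start times as float hours since ``origin`` (default: first bin)."""
        origin = self.t[0] if origin is None else np.datetime64(origin, "s")
        return (self.t - origin) / _HOUR

    def is_contiguous(self) -> bool:
        if len(self) == 1:
            return True
        step = np.timedelta64(int(round(self.bin_minutes * 60)), "s")
        return bool(np.all(np.diff(self.t) == step))
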