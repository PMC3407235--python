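"""Reading and writing actogram CSV files, schedule configs and cohort manifests.

The on-disk actogram dialect is a two-column CSV with header
``timestamp,count`` (ISO-8601 naive local timestamps, one row per 6-min bin).
Animal metadata travel in a JSON sidecar ``<stem>.meta.json`` keyed by
animal_id. A cohort manifest is a CSV with columns
``animal_id,photoperiod_L,etv,fur_score,mass,path``.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .schedule import ActivityRecord, AnimalMetadata, LightSchedule, build_schedule


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_activity(path, fmt: str = "csv") -> ActivityRecord:
    """Read a validated :class:`ActivityRecord` from an actogram CSV.

    The bin width is inferred from the smallest timestamp difference and
    checked to divide every gap; mixed spacings raise :class:`FormatError`.
    """
    if fmt != "csv":
        raise FormatError(f"unsupported format {fmt!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if df.empty:
        raise FormatError(f"{path} contains no data rows")
    if not {"timestamp", "count"} <= set(df.columns):
        raise FormatError(f"{path} lacks 'timestamp,count' header")
    try:
        t = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamps") from exc
    counts = df["count"].to_numpy()

    if t.size > 1:
        diffs = np.diff(t).astype("timedelta64[s]").astype(np.int64)
        if np.any(diffs <= 0):
            raise FormatError(f"{path}: timestamps not strictly increasing")
        step = diffs.min()
        if np.any(diffs % step != 0):
            raise FormatError(f"{path}: non-uniform bin spacing")
        bin_minutes = step / 60.0
    else:
        bin_minutes = 6.0

    meta = None
    sidecar = _sidecar_path(path)
    animal_id = path.stem
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        if len(blob) == 1:
            animal_id, fields = next(iter(blob.items()))
            meta = AnimalMetadata(**fields)
    try:
        return ActivityRecord(
            animal_id=animal_id, t=t, counts=counts, bin_minutes=bin_minutes, metadata=meta
        )
    except ValidationError:
        raise


def write_activity(record: ActivityRecord, path, fmt: str = "csv") -> Path:
    """Write a record to CSV (+ metadata sidecar); inverse of :func:`read_activity`."""
    if fmt != "csv":
        raise FormatError(f"unsupported format {fmt!r}")
    if len(record) == 0:  # pragma: no cover - unconstructible, guarded anyway
        raise ValidationError("refusing to write an empty record")
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(record.t).strftime("%Y-%m-%dT%H:%M:%S"),
            "count": record.counts,
        }
    )
    df.to_csv(path, index=False)
    if record.metadata is not None:
        _sidecar_path(path).write_text(
            json.dumps({record.animal_id: asdict(record.metadata)}, indent=1)
        )
    return path


def read_schedule(path) -> LightSchedule:
    """Read a schedule config YAML like ``{L: 13, lights_off: "18:00"}``."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "L" not in cfg:
        raise FormatError(f"{path}: schedule config must define 'L'")
    return build_schedule(cfg["L"], cfg.get("lights_off", "18:00"))


def write_schedule(schedule: LightSchedule, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({"L": schedule.L, "lights_off": schedule.lights_off}))
    return path


MANIFEST_COLUMNS = ["animal_id", "photoperiod_L", "etv", "fur_score", "mass", "path"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(rows: pd.DataFrame, path) -> Path:
    path = Path(path)
    rows.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
    return path


def metadata_from_row(row) -> AnimalMetadata:
    return AnimalMetadata(
        photoperiod_L=float(row["photoperiod_L"]),
        etv_week12=float(row["etv"]),
        fur_score=int(row["fur_score"]),
        body_mass=float(row["mass"]),
    )
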