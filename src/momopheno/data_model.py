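"""Unified event schema, readers/writers, and local-time handling.

Every sensor stream is a long-format table with the same leading columns
(``participant_id``, ``device_id``, ``timestamp_utc``, ``tz``) followed by
sensor-specific payload columns.  All behavioral binning downstream is done
in *local* time of a single study timezone, midnight-to-midnight, with
half-open hour bins: a bin ``[h, h+1)`` owns events with timestamp >= h and
< h+1.  Hour-of-week runs 0 (Monday 00:00-01:00) through 167 (Sunday
23:00-24:00).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns shared by every sensor table, in order.
BASE_COLUMNS = ["participant_id", "device_id", "timestamp_utc", "tz"]

#: Sensor-specific payload columns, in order.  Durations are in seconds.
SENSOR_PAYLOADS: dict[str, list[str]] = {
    "call": ["call_type", "call_duration"],
    "sms": ["message_type"],
    "screen": ["screen_status"],
    "app": ["application_name", "duration"],
    "location": ["latitude", "longitude", "speed", "accuracy"],
    "accelerometer": ["x", "y", "z"],
    "actigraph": ["activity_count", "status"],
    "bed": ["occupancy"],
    "battery": ["battery_level", "battery_status"],
}

SENSORS = tuple(SENSOR_PAYLOADS)

#: Closed vocabularies for categorical payload columns.
ENUM_VALUES: dict[tuple[str, str], frozenset[str]] = {
    ("call", "call_type"): frozenset({"incoming", "outgoing", "missed"}),
    ("sms", "message_type"): frozenset({"incoming", "outgoing"}),
    ("screen", "screen_status"): frozenset({"on", "off", "lock", "unlock"}),
    ("actigraph", "status"): frozenset({"active", "rest", "sleep"}),
    ("bed", "occupancy"): frozenset({"occupied", "free"}),
}

PHQ9_COLUMNS = ["participant_id", "response_date", "score", "period_index"]


class SchemaError(ValueError):
    """Raised when a table does not match its sensor schema."""


class TimestampError(ValueError):
    """Raised when timestamps cannot be parsed."""


def sensor_columns(sensor: str) -> list[str]:
    """Full ordered column list for ``sensor``."""
    if sensor not in SENSOR_PAYLOADS:
        raise SchemaError(f"unknown sensor {sensor!r}; expected one of {sorted(SENSOR_PAYLOADS)}")
    return BASE_COLUMNS + SENSOR_PAYLOADS[sensor]


def _normalize_enums(df: pd.DataFrame, sensor: str) -> pd.DataFrame:
    for (sens, col), allowed in ENUM_VALUES.items():
        if sens != sensor or col not in df.columns:
            continue
        vals = df[col].astype(str).str.strip().str.lower()
        bad = sorted(set(vals) - allowed)
        if bad:
            raise SchemaError(f"{sensor}.{col}: invalid values {bad}; allowed {sorted(allowed)}")
        df[col] = vals
    return df


def validate_events(df: pd.DataFrame, sensor: str) -> pd.DataFrame:
    """Validate, normalize, dedupe and sort a raw sensor table.

    Returns a copy with ``timestamp_utc`` as tz-aware UTC datetimes, enum
    payloads lower-cased/stripped, exact duplicate rows dropped (count
    logged), and rows sorted by (participant_id, timestamp_utc).
    """
    cols = sensor_columns(sensor)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{sensor} table missing columns {missing}")
    out = df.loc[:, cols].copy()
    ts = pd.to_datetime(out["timestamp_utc"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad_rows = out.index[ts.isna()].tolist()[:10]
        raise TimestampError(f"{sensor}: unparseable timestamps at rows {bad_rows}")
    out["timestamp_utc"] = ts
    out = _normalize_enums(out, sensor)
    n_before = len(out)
    out = out.drop_duplicates()
    n_dropped = n_before - len(out)
    if n_dropped:
        logger.info("%s: dropped %d exact duplicate rows", sensor, n_dropped)
    out = out.sort_values(["participant_id", "timestamp_utc"], kind="mergesort")
    return out.reset_index(drop=True)


def read_events(path: str | Path, sensor: str) -> pd.DataFrame:
    """Read and validate one sensor stream from CSV (or parquet)."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return validate_events(df, sensor)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sensor table as UTF-8 CSV with ISO-8601 timestamps, or parquet."""
    path = Path(path)
    out = df.copy()
    if path.suffix == ".parquet":
        out.to_parquet(path, index=False)
        return
    if pd.api.types.is_datetime64_any_dtype(out["timestamp_utc"]):
        out["timestamp_utc"] = out["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def localize(df: pd.DataFrame, tz: str) -> pd.DataFrame:
    """Add local-clock columns resolved by the zone's rules (incl. DST).

    Adds ``timestamp_local``, ``local_date``, ``local_hour`` and
    ``hour_of_week`` (= weekday*24 + hour, Monday 00 local = 0).
    """
    try:
        local = df["timestamp_utc"].dt.tz_convert(tz)
    except Exception as exc:  # zoneinfo raises on unknown zones
        raise ValueError(f"unknown or invalid timezone {tz!r}") from exc
    out = df.copy()
    out["timestamp_local"] = local
    out["local_date"] = local.dt.normalize().dt.tz_localize(None)
    out["local_hour"] = local.dt.hour
    out["hour_of_week"] = local.dt.weekday * 24 + local.dt.hour
    return out


def validate_phq9(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a PHQ-9 response table (score 0-27, non-negative period index)."""
    missing = [c for c in PHQ9_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phq9 table missing columns {missing}")
    out = df.loc[:, PHQ9_COLUMNS].copy()
    out["response_date"] = pd.to_datetime(out["response_date"])
    out["score"] = out["score"].astype(int)
    if ((out["score"] < 0) | (out["score"] > 27)).any():
        raise SchemaError("phq9 scores must lie in [0, 27]")
    if (out["period_index"] < 0).any():
        raise SchemaError("period_index must be >= 0")
    return out.sort_values(["participant_id", "response_date"]).reset_index(drop=True)


def read_phq9(path: str | Path) -> pd.DataFrame:
    return validate_phq9(pd.read_csv(path))


def concat_streams(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-participant tables of one sensor, re-sorting canonically."""
    df = pd.concat(list(tables), ignore_index=True)
    return df.sort_values(["participant_id", "timestamp_utc"], kind="mergesort").reset_index(
        drop=True
    )
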