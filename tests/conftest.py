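"""Shared fixtures: tiny hand-built event tables in study-local time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

TZ = "Europe/Helsinki"


def local_events(times, tz: str = TZ, pid: str = "p01", **payload) -> pd.DataFrame:
    """Event table from local wall-clock timestamps, localized for analysis.

    ``times``: iterable of strings/timestamps interpreted in ``tz``.
    Payload columns are broadcast or aligned per event.
    """
    from momopheno import data_model

    idx = pd.DatetimeIndex(pd.to_datetime(list(times))).tz_localize(tz)
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "device_id": f"dev-{pid}",
            "timestamp_utc": idx.tz_convert("UTC"),
            "tz": tz,
        }
    )
    for col, val in payload.items():
        df[col] = val
    return data_model.localize(df, tz)


def epoch_table(start, statuses, epoch_s: float = 30.0, pid: str = "p01",
                status_col: str = "status", tz: str = TZ) -> pd.DataFrame:
    """Epoch stream from a status sequence starting at a local instant."""
    start = pd.Timestamp(start)
    times = start + pd.to_timedelta(np.arange(len(statuses)) * epoch_s, unit="s")
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp_local": pd.DatetimeIndex(times).tz_localize(tz),
            status_col: list(statuses),
        }
    )
    df["local_date"] = df["timestamp_local"].dt.tz_localize(None).dt.normalize()
    return df


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group, 4-participant cohort with short streams (session-cached)."""
    from momopheno import synthetic_data as sd

    config = sd.CohortConfig(
        n_per_group={"control": 2, "mdd": 2},
        group_labels=("control", "mdd"),
        study_days=28,
        seed=7,
        active_phase_days=2,
    )
    effects = sd.PlantedEffects()
    cohort = sd.generate_cohort(config, effects)
    return config, effects, cohort
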