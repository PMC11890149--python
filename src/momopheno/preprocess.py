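"""Filtering and hourly/daily aggregation of smartphone streams.

Rules applied, in order, for the behavioral analyses: drop each
participant's first and last observed local date (incomplete capture),
restrict to the first 8 weeks of calendar days, drop implausible app
sessions (>10 h, strictly), then bin events into participant x local-date x
hour counts and durations.  Counts use half-open hour bins; sample SD
(divisor n-1) is used throughout.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Manual app categories; any app not in the map is "uncategorized".
APP_CATEGORIES = (
    "sports", "communication", "leisure", "social media", "work",
    "news", "shop", "transport", "utility", "games", "uncategorized",
)

#: Missing off-event guard: a screen session longer than this is truncated.
SCREEN_SESSION_CAP_S = 2 * 3600.0


def trim_first_last_day(table: pd.DataFrame) -> pd.DataFrame:
    """Drop each participant's first and last observed local date.

    Participants with <= 2 observed days lose all rows (warning logged).
    """
    if table.empty:
        return table.copy()
    firsts = table.groupby("participant_id")["local_date"].transform("min")
    lasts = table.groupby("participant_id")["local_date"].transform("max")
    keep = (table["local_date"] > firsts) & (table["local_date"] < lasts)
    emptied = set(table["participant_id"]) - set(table.loc[keep, "participant_id"])
    if emptied:
        logger.warning("trim_first_last_day removed all rows for %d participants", len(emptied))
    return table.loc[keep].reset_index(drop=True)


def restrict_to_weeks(table: pd.DataFrame, n_weeks: int = 8) -> tuple[pd.DataFrame, list[str]]:
    """Keep each participant's first ``n_weeks*7`` calendar days after trimming.

    Participants whose observed calendar span is shorter than the window are
    dropped entirely (they fail the minimum-data eligibility rule for rhythm
    analyses); their ids are returned alongside the filtered table.
    """
    if table.empty:
        return table.copy(), []
    window = pd.Timedelta(days=n_weeks * 7)
    firsts = table.groupby("participant_id")["local_date"].transform("min")
    spans = table.groupby("participant_id")["local_date"].transform("max") - firsts
    eligible = spans >= window - pd.Timedelta(days=1)
    in_window = table["local_date"] < firsts + window
    dropped = sorted(set(table.loc[~eligible, "participant_id"]))
    if dropped:
        logger.info("restrict_to_weeks: %d participants below %d weeks of data", len(dropped), n_weeks)
    return table.loc[eligible & in_window].reset_index(drop=True), dropped


def filter_app_durations(
    app_table: pd.DataFrame, max_hours: float = 10.0
) -> tuple[pd.DataFrame, int]:
    """Remove likely-erroneous app sessions with duration > ``max_hours``.

    The cutoff is strict: a session of exactly ``max_hours`` survives.
    Negative durations are invalid and removed too.  Returns the filtered
    table and the number of rows removed.
    """
    dur_h = app_table["duration"] / 3600.0
    bad = (dur_h > max_hours) | (app_table["duration"] < 0)
    n_removed = int(bad.sum())
    if n_removed:
        logger.info("filter_app_durations removed %d rows", n_removed)
    return app_table.loc[~bad].reset_index(drop=True), n_removed


def positive_duration_fraction(call_table: pd.DataFrame) -> float:
    """Fraction of calls with duration > 0 s (answered incoming/outgoing)."""
    if len(call_table) == 0:
        raise ValueError("empty call table")
    return float((call_table["call_duration"] > 0).mean())


def map_app_categories(app_table: pd.DataFrame, category_map: dict[str, str]) -> pd.DataFrame:
    """Attach a ``category`` column; unmapped apps become "uncategorized"."""
    out = app_table.copy()
    out["category"] = out["application_name"].map(category_map).fillna("uncategorized")
    return out


def screen_sessions(screen_table: pd.DataFrame) -> pd.DataFrame:
    """Pair screen use-episode starts (on/unlock) with ends (off/lock).

    Session duration = time to the participant's next off/lock event, capped
    at 2 h as a guard against missing off-events (cap count logged).
    Returns one row per episode with ``duration`` in seconds.
    """
    rows = []
    n_capped = 0
    for pid, g in screen_table.groupby("participant_id"):
        g = g.sort_values("timestamp_utc")
        ts = g["timestamp_utc"].to_numpy()
        status = g["screen_status"].to_numpy()
        is_start = np.isin(status, ("on", "unlock"))
        is_end = np.isin(status, ("off", "lock"))
        end_times = ts[is_end]
        for t in ts[is_start]:
            later = end_times[end_times > t]
            if len(later):
                dur = (later[0] - t) / np.timedelta64(1, "s")
            else:
                dur = SCREEN_SESSION_CAP_S
            if dur > SCREEN_SESSION_CAP_S:
                dur = SCREEN_SESSION_CAP_S
                n_capped += 1
            rows.append({"participant_id": pid, "timestamp_utc": t, "duration": dur})
    if n_capped:
        logger.info("screen_sessions capped %d sessions at 2 h", n_capped)
    out = pd.DataFrame(rows, columns=["participant_id", "timestamp_utc", "duration"])
    if not out.empty:
        out["timestamp_utc"] = pd.DatetimeIndex(out["timestamp_utc"])
    return out


def hourly_counts(
    table: pd.DataFrame,
    by_category: str | None = None,
    duration_col: str | None = None,
) -> pd.DataFrame:
    """Counts (and summed duration, minutes) per participant x date x hour.

    ``by_category`` names a column to split on (e.g. ``call_type`` or
    ``category``); ``duration_col`` a seconds-valued column to sum.  Hours
    with no events are absent (implicitly zero).
    """
    keys = ["participant_id", "local_date", "local_hour"]
    if "hour_of_week" in table.columns:
        keys.append("hour_of_week")
    if by_category:
        keys.append(by_category)
    grouped = table.groupby(keys, observed=True)
    out = grouped.size().rename("count").reset_index()
    if duration_col:
        dur = grouped[duration_col].sum().rename("duration_min").reset_index()
        out = out.merge(dur, on=keys)
        out["duration_min"] = out["duration_min"] / 60.0
    return out


def accel_magnitude_sd(samples: pd.DataFrame) -> pd.DataFrame:
    """Hourly SD of mean-centered accelerometer magnitude.

    magnitude = sqrt(x^2 + y^2 + z^2), centered by subtracting each
    participant's overall mean magnitude; the per-hour sample SD (ddof=1) is
    the physical-activity proxy.  Hours with fewer than 2 samples are
    omitted (missing).
    """
    df = samples.copy()
    df["magnitude"] = np.sqrt(df["x"] ** 2 + df["y"] ** 2 + df["z"] ** 2)
    df["magnitude"] -= df.groupby("participant_id")["magnitude"].transform("mean")
    keys = ["participant_id", "local_date", "local_hour"]
    if "hour_of_week" in df.columns:
        keys.append("hour_of_week")
    agg = df.groupby(keys)["magnitude"].agg(["std", "size"]).reset_index()
    agg = agg[agg["size"] >= 2]
    return agg.rename(columns={"std": "magnitude_sd"}).drop(columns="size").reset_index(drop=True)


def daily_means(
    hourly: pd.DataFrame, value: str = "count", by_category: str | None = None
) -> pd.DataFrame:
    """Per-participant daily totals, then the mean across days.

    Missing hours contribute nothing (the daily total sums observed hours);
    days with no rows at all are absent rather than zero.
    """
    keys = ["participant_id", "local_date"] + ([by_category] if by_category else [])
    daily = hourly.groupby(keys, observed=True)[value].sum().reset_index()
    keys2 = ["participant_id"] + ([by_category] if by_category else [])
    return daily.groupby(keys2, observed=True)[value].mean().rename("daily_mean").reset_index()


def group_summary(
    per_participant: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    value: str = "daily_mean",
    by_category: str | None = None,
    group_a: str = "control",
) -> pd.DataFrame:
    """Group mean (SD) table with between-group MWU P values, BH-adjusted.

    ``groups`` maps participant_id -> group label (two groups expected,
    e.g. control vs patient).  One row per category (or a single row).
    """
    from .rhythms import bh_adjust, mwu_test

    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("participant_id")["group"]
    df = per_participant.copy()
    df["group"] = df["participant_id"].map(groups)
    labels = sorted(df["group"].dropna().unique(), key=lambda g: (g != group_a, g))
    if len(labels) != 2:
        raise ValueError(f"group_summary expects exactly 2 groups, got {labels}")
    cats = df[by_category].unique() if by_category else [None]
    rows = []
    for cat in cats:
        sub = df if cat is None else df[df[by_category] == cat]
        a = sub.loc[sub["group"] == labels[0], value].to_numpy()
        b = sub.loc[sub["group"] == labels[1], value].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        u, p = mwu_test(a, b)
        rows.append(
            {
                "feature": cat if cat is not None else value,
                f"{labels[0]}_mean": a.mean(),
                f"{labels[0]}_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"{labels[1]}_mean": b.mean(),
                f"{labels[1]}_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
                "U": u,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out
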