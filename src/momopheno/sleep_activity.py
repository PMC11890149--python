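"""Per-night sleep variables and daily active hours from epoch streams.

Actigraph epochs (30 s) carry a device-scored status (active / rest /
sleep); the bed sensor emits 1-s occupancy epochs (occupied / free).  A
"night" spans local noon to the next local noon and is attributed to the
date it starts, so sleep is never split at midnight.

Scoring rules:

* bedtime = start of the first run of >= 3 consecutive minutes of "sleep"
  epochs in the night window;
* waketime = start of the first >= 3-minute run of "active" epochs after
  bedtime (within the same night window);
* bed sensor: the sleep period is the single longest maximal occupied run
  (ties broken toward the earlier run);
* a gap of more than 5 minutes between consecutive epochs breaks any run,
  so missing data cannot fabricate continuity;
* per participant the first and last scored nights are dropped, as are
  nights shorter than 3 h or longer than 13 h (both bounds strict, so
  exactly 3 h or 13 h survives).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_GAP = pd.Timedelta(minutes=5)
MIN_RUN = pd.Timedelta(minutes=3)

SLEEP_MIN_H = 3.0
SLEEP_MAX_H = 13.0


def _naive(ts: pd.Series) -> pd.Series:
    """Local wall-clock time as naive datetimes (run logic is wall-clock)."""
    if isinstance(ts.dtype, pd.DatetimeTZDtype):
        return ts.dt.tz_localize(None)
    return pd.to_datetime(ts)


def _night_date(ts: pd.Series) -> pd.Series:
    """Date a local instant's night window is attributed to (noon-to-noon)."""
    return (_naive(ts) - pd.Timedelta(hours=12)).dt.normalize()


def _runs(times: np.ndarray, mask: np.ndarray, epoch: np.timedelta64) -> list[tuple[int, int]]:
    """Maximal runs of True epochs, broken by False epochs or gaps > 5 min.

    Returns (start_index, end_index_inclusive) pairs in time order.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    gap_ns = MAX_GAP.value
    breaks = np.flatnonzero(
        (np.diff(idx) != 1)
        | ((times[idx[1:]] - times[idx[:-1]]).astype("timedelta64[ns]").astype("int64") > gap_ns)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _epoch_length(times: np.ndarray, default_s: float) -> np.timedelta64:
    if len(times) < 2:
        return np.timedelta64(int(default_s * 1e9), "ns")
    diffs = np.diff(times).astype("timedelta64[ns]")
    return np.median(diffs).astype("timedelta64[ns]")


def _run_duration(times, start, end, epoch) -> pd.Timedelta:
    return pd.Timedelta(times[end] - times[start]) + pd.Timedelta(epoch)


def actigraph_sleep(epochs: pd.DataFrame) -> pd.DataFrame:
    """Score one sleep period per night window from actigraph statuses.

    Input must be localized (``timestamp_local``) with a ``status`` column.
    Nights with no qualifying >= 3-min sleep run (or no subsequent wake run)
    are emitted with NaT times and a ``reason`` code.
    """
    df = epochs.copy()
    df["_t"] = _naive(df["timestamp_local"])
    df["night_date"] = _night_date(df["timestamp_local"])
    rows = []
    for (pid, night), g in df.groupby(["participant_id", "night_date"], sort=True):
        g = g.sort_values("_t")
        times = g["_t"].to_numpy()
        status = g["status"].to_numpy()
        epoch = _epoch_length(times, 30.0)
        min_epochs = max(int(np.ceil(MIN_RUN / pd.Timedelta(epoch))), 1)
        bedtime = waketime = pd.NaT
        reason = ""
        for s, e in _runs(times, status == "sleep", epoch):
            if e - s + 1 >= min_epochs:
                bedtime = pd.Timestamp(times[s])
                break
        if bedtime is pd.NaT:
            reason = "no_sleep_run"
        else:
            after = times > np.datetime64(bedtime)
            for s, e in _runs(times, (status == "active") & after, epoch):
                if e - s + 1 >= min_epochs:
                    waketime = pd.Timestamp(times[s])
                    break
            if waketime is pd.NaT:
                reason = "no_wake_run"
        duration = (waketime - bedtime).total_seconds() / 3600.0 if reason == "" else np.nan
        rows.append(
            {
                "participant_id": pid,
                "night_date": night,
                "bedtime": bedtime,
                "waketime": waketime,
                "duration_h": duration,
                "source": "actigraph",
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def actigraph_active_hours(epochs: pd.DataFrame, epoch_seconds: float = 30.0) -> pd.DataFrame:
    """Active hours per local calendar date: (#'active' epochs) * epoch / 3600."""
    df = epochs.copy()
    active = df[df["status"] == "active"]
    counts = (
        active.groupby(["participant_id", "local_date"]).size().rename("n_active").reset_index()
    )
    all_days = df[["participant_id", "local_date"]].drop_duplicates()
    out = all_days.merge(counts, how="left").fillna({"n_active": 0})
    out["active_hours"] = out["n_active"] * epoch_seconds / 3600.0
    return out.drop(columns="n_active").sort_values(["participant_id", "local_date"]).reset_index(
        drop=True
    )


def bed_sleep(epochs: pd.DataFrame) -> pd.DataFrame:
    """Sleep period per night = the longest maximal bed-occupied run.

    Equal-length runs break ties toward the earlier one.  Nights with no
    occupied epochs are emitted as missing.
    """
    df = epochs.copy()
    df["_t"] = _naive(df["timestamp_local"])
    df["night_date"] = _night_date(df["timestamp_local"])
    rows = []
    for (pid, night), g in df.groupby(["participant_id", "night_date"], sort=True):
        g = g.sort_values("_t")
        times = g["_t"].to_numpy()
        occ = g["occupancy"].to_numpy()
        epoch = _epoch_length(times, 1.0)
        best = None
        best_dur = pd.Timedelta(0)
        for s, e in _runs(times, occ == "occupied", epoch):
            dur = _run_duration(times, s, e, epoch)
            if dur > best_dur:  # strict: earlier run wins ties
                best, best_dur = (s, e), dur
        if best is None:
            rows.append(
                {
                    "participant_id": pid,
                    "night_date": night,
                    "bedtime": pd.NaT,
                    "waketime": pd.NaT,
                    "duration_h": np.nan,
                    "source": "bed",
                    "reason": "no_occupancy",
                }
            )
            continue
        s, e = best
        bedtime = pd.Timestamp(times[s])
        waketime = pd.Timestamp(times[e]) + pd.Timedelta(epoch)
        rows.append(
            {
                "participant_id": pid,
                "night_date": night,
                "bedtime": bedtime,
                "waketime": waketime,
                "duration_h": (waketime - bedtime).total_seconds() / 3600.0,
                "source": "bed",
                "reason": "",
            }
        )
    return pd.DataFrame(rows)


def filter_nights(nights: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop first/last nights and implausible durations per participant.

    Durations < 3 h or > 13 h are omitted (strict bounds).  Returns the
    surviving nights and counts of removals by reason.
    """
    df = nights[nights["reason"] == ""].copy() if "reason" in nights.columns else nights.copy()
    n_unscored = len(nights) - len(df)
    removed = {"unscored": n_unscored, "first_last": 0, "duration": 0}
    keep_frames = []
    for (pid, src), g in df.groupby(["participant_id", "source"]):
        g = g.sort_values("night_date")
        inner = g.iloc[1:-1] if len(g) > 2 else g.iloc[0:0]
        removed["first_last"] += len(g) - len(inner)
        ok = (inner["duration_h"] >= SLEEP_MIN_H) & (inner["duration_h"] <= SLEEP_MAX_H)
        removed["duration"] += int((~ok).sum())
        keep_frames.append(inner[ok])
    out = (
        pd.concat(keep_frames, ignore_index=True)
        if keep_frames
        else df.iloc[0:0].reset_index(drop=True)
    )
    assert out.empty or (
        (out["duration_h"] >= SLEEP_MIN_H) & (out["duration_h"] <= SLEEP_MAX_H)
    ).all()
    return out, removed
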