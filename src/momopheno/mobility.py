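"""Daily GPS mobility features.

From raw fixes to, per participant and local date: log location variance,
raw and normalized location entropy, distance traveled, number of
significant places visited, and fraction of time at home — plus
weekday/weekend group summaries.

All thresholds are package defaults, exposed in :class:`MobilityConfig`:
fixes worse than 100 m accuracy are dropped; fixes are downsampled to one
per 10-minute bin (median coordinates); a binned fix is stationary if
reported speed < 1 m/s (or, lacking speed, displacement to the previous
binned fix < 100 m); significant places are density clusters of stationary
fixes (haversine radius 100 m, minimum 5 fixes); days with fewer than 6
binned fixes yield no features.

Feature definitions:

* log location variance = ln(var(lat) + var(lon)) over the day's binned
  fixes (sample variance in squared degrees; a 1e-12 floor inside the log
  guards degenerate days);
* location entropy H = -sum p_k ln p_k over time fractions spent in each
  significant place visited that day; the normalized variant divides by
  ln(total number of the participant's significant places);
* home = the significant place holding most of the participant's binned
  fixes between 00:00 and 06:00 over the whole observation span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

EARTH_RADIUS_M = 6_371_000.0
LOG_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class MobilityConfig:
    accuracy_max_m: float = 100.0
    bin_minutes: int = 10
    stationary_speed_ms: float = 1.0
    stationary_disp_m: float = 100.0
    cluster_radius_m: float = 100.0
    cluster_min_fixes: int = 5
    min_bins_per_day: int = 6
    home_hours: tuple[int, int] = (0, 6)


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters (array-capable)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def preprocess_gps(fixes: pd.DataFrame, config: MobilityConfig = MobilityConfig()) -> pd.DataFrame:
    """Accuracy-filter, downsample to 10-min bins, flag stationary fixes.

    Input must be localized.  Output: one row per participant per bin with
    median lat/lon, bin start (local), local_date, local_hour, stationary.
    """
    df = fixes.copy()
    if "accuracy" in df.columns:
        df = df[df["accuracy"].isna() | (df["accuracy"] <= config.accuracy_max_m)]
    df["_bin"] = df["timestamp_local"].dt.floor(f"{config.bin_minutes}min")
    agg = {"latitude": "median", "longitude": "median"}
    if "speed" in df.columns:
        agg["speed"] = "median"
    binned = df.groupby(["participant_id", "_bin"]).agg(agg).reset_index()
    binned = binned.sort_values(["participant_id", "_bin"]).reset_index(drop=True)
    binned = binned.rename(columns={"_bin": "bin_local"})
    binned["local_date"] = binned["bin_local"].dt.tz_localize(None).dt.normalize()
    binned["local_hour"] = binned["bin_local"].dt.hour
    if "speed" in binned.columns and binned["speed"].notna().any():
        stationary = binned["speed"] < config.stationary_speed_ms
    else:
        prev_lat = binned.groupby("participant_id")["latitude"].shift()
        prev_lon = binned.groupby("participant_id")["longitude"].shift()
        disp = haversine_m(binned["latitude"], binned["longitude"], prev_lat, prev_lon)
        stationary = pd.Series(disp, index=binned.index).fillna(0.0) < config.stationary_disp_m
    binned["stationary"] = stationary.to_numpy()
    return binned


def significant_places(
    binned: pd.DataFrame, config: MobilityConfig = MobilityConfig()
) -> pd.DataFrame:
    """Label each binned fix with a significant-place id (or -1 = transient).

    Density clustering (DBSCAN, haversine metric) over each participant's
    stationary fixes across the whole observation span; moving fixes are
    transient by definition.  Deterministic given the (sorted) input.
    """
    out = binned.copy()
    out["place"] = -1
    for pid, g in out.groupby("participant_id"):
        stat = g[g["stationary"]]
        if len(stat) == 0:
            continue
        coords = np.radians(stat[["latitude", "longitude"]].to_numpy())
        db = DBSCAN(
            eps=config.cluster_radius_m / EARTH_RADIUS_M,
            min_samples=config.cluster_min_fixes,
            metric="haversine",
        ).fit(coords)
        out.loc[stat.index, "place"] = db.labels_
    return out


def location_variance(day_fixes: pd.DataFrame) -> float:
    """ln(var(lat) + var(lon)) over a day's binned fixes; NaN if < 2 fixes."""
    if len(day_fixes) < 2:
        return np.nan
    v = day_fixes["latitude"].var(ddof=1) + day_fixes["longitude"].var(ddof=1)
    return float(np.log(max(v, LOG_VAR_FLOOR)))


def location_entropy(day_labels: pd.Series, k_total: int) -> tuple[float, float]:
    """(raw H, normalized H) over time fractions in significant places.

    Fractions are over the day's fixes that lie in a significant place;
    normalization divides by ln(k_total) (0 when k_total <= 1).
    """
    labs = day_labels[day_labels >= 0]
    if len(labs) == 0:
        return np.nan, np.nan
    p = labs.value_counts(normalize=True).to_numpy()
    h = float(-(p * np.log(p)).sum())
    h_norm = h / np.log(k_total) if k_total > 1 else 0.0
    return h, float(h_norm)


def day_distance_km(day_fixes: pd.DataFrame) -> float:
    """Sum of haversine distances between consecutive binned fixes, km."""
    if len(day_fixes) < 2:
        return 0.0
    lat = day_fixes["latitude"].to_numpy()
    lon = day_fixes["longitude"].to_numpy()
    return float(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum() / 1000.0)


def home_place(labeled: pd.DataFrame, config: MobilityConfig = MobilityConfig()) -> dict[str, int]:
    """Per participant: the place with most fixes in the night hours."""
    lo, hi = config.home_hours
    night = labeled[(labeled["local_hour"] >= lo) & (labeled["local_hour"] < hi) & (labeled["place"] >= 0)]
    homes = {}
    for pid, g in night.groupby("participant_id"):
        homes[pid] = int(g["place"].value_counts().idxmax())
    return homes


def mobility_daily(
    fixes: pd.DataFrame, config: MobilityConfig = MobilityConfig()
) -> pd.DataFrame:
    """Full daily mobility feature table from localized raw fixes."""
    binned = preprocess_gps(fixes, config)
    labeled = significant_places(binned, config)
    homes = home_place(labeled, config)
    rows = []
    for pid, g in labeled.groupby("participant_id"):
        k_total = int((g["place"].max() + 1) if (g["place"] >= 0).any() else 0)
        home = homes.get(pid)
        for date, day in g.groupby("local_date"):
            if len(day) < config.min_bins_per_day:
                continue
            h, h_norm = location_entropy(day["place"], k_total)
            rows.append(
                {
                    "participant_id": pid,
                    "local_date": date,
                    "is_weekday": date.weekday() < 5,
                    "log_location_variance": location_variance(day),
                    "entropy": h,
                    "normalized_entropy": h_norm,
                    "distance_km": day_distance_km(day),
                    "n_significant_places": int(day.loc[day["place"] >= 0, "place"].nunique()),
                    "pct_time_home": (
                        float((day["place"] == home).mean()) if home is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


FEATURES = (
    "log_location_variance",
    "entropy",
    "normalized_entropy",
    "distance_km",
    "n_significant_places",
    "pct_time_home",
)


def weekday_weekend_split(
    daily: pd.DataFrame, groups: pd.Series | pd.DataFrame, group_a: str = "control"
) -> pd.DataFrame:
    """Group mean (SD) and MWU P per feature, weekdays and weekends apart.

    Per-participant means are computed separately over Mon-Fri and Sat-Sun
    days, then compared between the two groups; P values are BH-adjusted
    within each day-type family.
    """
    from .rhythms import bh_adjust, mwu_test

    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("participant_id")["group"]
    rows = []
    for is_weekday, tag in ((True, "weekday"), (False, "weekend")):
        sub = daily[daily["is_weekday"] == is_weekday]
        per = sub.groupby("participant_id")[list(FEATURES)].mean()
        per["group"] = per.index.map(groups)
        labels = sorted(per["group"].dropna().unique(), key=lambda g: (g != group_a, g))
        if len(labels) != 2:
            continue
        for feat in FEATURES:
            a = per.loc[per["group"] == labels[0], feat].dropna().to_numpy()
            b = per.loc[per["group"] == labels[1], feat].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0:
                continue
            u, p = mwu_test(a, b)
            rows.append(
                {
                    "day_type": tag,
                    "feature": feat,
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
        out["p_adj"] = np.nan
        for tag in out["day_type"].unique():
            m = out["day_type"] == tag
            out.loc[m, "p_adj"] = bh_adjust(out.loc[m, "p_raw"].to_numpy())
    return out
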