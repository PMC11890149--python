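"""End-to-end pipeline: raw streams -> features -> analysis tables.

``run_pipeline`` reads the per-sensor stream files plus the participant
registry and PHQ-9 responses from an input directory, applies the
preprocessing rules, and writes the analysis surfaces: group summary tables
(daily communication / app-use volumes), the within-group rhythm
homogeneity table, mobility weekday/weekend summaries, sleep nights and
daily activity, adherence series with Kaplan-Meier curves and a log-rank
comparison, the mixed-model association tables, and a JSON manifest with
row counts, filter-removal counts and software versions.

Patient subcohorts (MDD, BD, BPD) are collapsed into a single "patient"
group for all two-group comparisons; the subcohort labels are kept for
adherence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adherence, association, data_model, mobility, preprocess, rhythms
from . import sleep_activity
from .synthetic_data import APP_CATALOG

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    timezone: str = "Europe/Helsinki"
    seed: int = 0
    n_weeks: int = 8
    window_days: int = 14
    period_days: int = 14
    employed_only: bool = False
    mobility: mobility.MobilityConfig = field(default_factory=mobility.MobilityConfig)
    app_category_map: dict[str, str] = field(default_factory=lambda: dict(APP_CATALOG))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mob = mobility.MobilityConfig(**raw.pop("mobility", {}))
        raw["input_dir"] = Path(raw["input_dir"])
        raw["output_dir"] = Path(raw["output_dir"])
        return cls(mobility=mob, **raw)


def cohort_composition(registry: pd.DataFrame,
                       patient_groups: tuple[str, ...] = ("mdd", "bd", "bpd")) -> pd.DataFrame:
    """Subcohort shares among the pooled patient group.

    One row per patient subcohort with its count and its fraction of all
    patients (controls excluded from the denominator).
    """
    patients = registry[registry["group"].isin(patient_groups)]
    n_pat = len(patients)
    if n_pat == 0:
        raise ValueError("registry contains no patient-group participants")
    counts = patients["group"].value_counts()
    return pd.DataFrame(
        {"group": counts.index, "n": counts.to_numpy(),
         "fraction_of_patients": counts.to_numpy() / n_pat}
    ).reset_index(drop=True)


def _two_group(registry: pd.DataFrame) -> pd.Series:
    g = registry.set_index("participant_id")["group"]
    return g.where(g == "control", "patient")


def _load_streams(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    streams = {}
    for sensor in data_model.SENSORS:
        for ext in ("csv", "parquet"):
            p = cfg.input_dir / f"{sensor}.{ext}"
            if p.exists():
                streams[sensor] = data_model.localize(
                    data_model.read_events(p, sensor), cfg.timezone
                )
                break
    return streams


def _daily_durations(hourly: pd.DataFrame, by: str) -> pd.DataFrame:
    """participant x local_date x category daily duration (min) wide table."""
    daily = (
        hourly.groupby(["participant_id", "local_date", by], observed=True)["duration_min"]
        .sum()
        .unstack(by)
        .reset_index()
    )
    daily.columns.name = None
    return daily


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every analysis stage; returns the manifest dictionary."""
    out = Path(cfg.output_dir)
    inter = out / "intermediate"
    inter.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"filters": {}, "rows_in": {}, "outputs": [], "failures": [], "skipped": []}

    registry = pd.read_csv(cfg.input_dir / "registry.csv", parse_dates=["enroll_date", "exit_date"])
    phq9 = data_model.read_phq9(cfg.input_dir / "phq9.csv")
    streams = _load_streams(cfg)
    manifest["rows_in"] = {s: int(len(df)) for s, df in streams.items()}
    groups2 = _two_group(registry)
    employment = registry.set_index("participant_id")["employment"]

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    # --- communication / screen / app preprocessing ------------------------
    trimmed: dict[str, pd.DataFrame] = {}
    restricted: dict[str, pd.DataFrame] = {}
    for sensor in ("call", "sms", "screen", "app", "accelerometer"):
        if sensor not in streams:
            continue
        t = preprocess.trim_first_last_day(streams[sensor])
        manifest["filters"][f"{sensor}_trim_first_last"] = {
            "in": int(len(streams[sensor])), "kept": int(len(t)),
            "removed": int(len(streams[sensor]) - len(t)),
        }
        trimmed[sensor] = t
        r, dropped = preprocess.restrict_to_weeks(t, cfg.n_weeks)
        manifest["filters"][f"{sensor}_restrict_{cfg.n_weeks}w"] = {
            "in": int(len(t)), "kept": int(len(r)), "removed": int(len(t) - len(r)),
            "participants_dropped": dropped,
        }
        restricted[sensor] = r

    if "app" in restricted:
        filtered, n_removed = preprocess.filter_app_durations(restricted["app"])
        manifest["filters"]["app_duration_gt_10h"] = {
            "in": int(len(restricted["app"])), "kept": int(len(filtered)), "removed": n_removed,
        }
        restricted["app"] = preprocess.map_app_categories(filtered, cfg.app_category_map)

    # --- daily group summaries (communication & app use) -------------------
    summaries = [
        ("call", "call_type", "call_duration", "count", "table_daily_calls.csv"),
        ("sms", "message_type", None, "count", "table_daily_sms.csv"),
        ("app", "category", "duration", "duration_min", "table_daily_app_use.csv"),
    ]
    for sensor, by, dur_col, value, fname in summaries:
        if sensor not in restricted or restricted[sensor].empty:
            continue
        try:
            hourly = preprocess.hourly_counts(restricted[sensor], by, dur_col)
            save(
                preprocess.group_summary(
                    preprocess.daily_means(hourly, value, by), groups2, by_category=by
                ),
                fname,
            )
        except ValueError as exc:  # e.g. only one group survives the filters
            manifest["skipped"].append(f"{fname}: {exc}")
        except Exception as exc:
            logger.exception("daily summary stage failed for %s", sensor)
            manifest["failures"].append(f"daily_summaries_{sensor}: {exc}")

    # --- weekly rhythms & homogeneity --------------------------------------
    try:
        rhythm_frames: dict[str, pd.DataFrame] = {}
        for sensor, act in (("call", "call"), ("sms", "sms"), ("screen", "screen")):
            if sensor in restricted and not restricted[sensor].empty:
                frame = rhythms.rhythm_table(preprocess.hourly_counts(restricted[sensor]))
                if not frame.empty:
                    rhythm_frames[act] = frame
        if "accelerometer" in restricted and not restricted["accelerometer"].empty:
            sd = preprocess.accel_magnitude_sd(restricted["accelerometer"])
            frame = rhythms.rhythm_table(sd.rename(columns={"magnitude_sd": "count"}))
            if not frame.empty:
                rhythm_frames["accel"] = frame
        long_rows = []
        for act, frame in rhythm_frames.items():
            frame = frame.copy()
            frame["group"] = frame["participant_id"].map(groups2)
            rhythm_frames[act] = frame
            melted = frame.melt(
                id_vars=["participant_id", "group", "all_zero"],
                value_vars=rhythms.WEIGHT_COLUMNS, var_name="bin", value_name="weight",
            )
            melted["activity_type"] = act
            long_rows.append(melted)
        if long_rows:
            save(pd.concat(long_rows, ignore_index=True), "rhythms.csv")
            usable = {
                a: f for a, f in rhythm_frames.items()
                if f.loc[~f["all_zero"], "group"].value_counts().ge(2).sum() >= 2
            }
            if usable:
                save(
                    rhythms.homogeneity_report(
                        usable, employment=employment, employed_only=cfg.employed_only
                    ),
                    "homogeneity.csv",
                )
    except Exception as exc:
        logger.exception("rhythm stage failed")
        manifest["failures"].append(f"rhythms: {exc}")

    # --- mobility -----------------------------------------------------------
    mob_daily = pd.DataFrame()
    try:
        if "location" in streams:
            mob_daily = mobility.mobility_daily(streams["location"], cfg.mobility)
            save(mob_daily, "mobility_daily.csv")
            split = mobility.weekday_weekend_split(mob_daily, groups2)
            save(split, "mobility_group_summary.csv")
    except Exception as exc:
        logger.exception("mobility stage failed")
        manifest["failures"].append(f"mobility: {exc}")

    # --- sleep & activity ----------------------------------------------------
    try:
        nights_frames = []
        if "actigraph" in streams:
            nights_frames.append(sleep_activity.actigraph_sleep(streams["actigraph"]))
            save(sleep_activity.actigraph_active_hours(streams["actigraph"]), "daily_activity.csv")
        if "bed" in streams:
            nights_frames.append(sleep_activity.bed_sleep(streams["bed"]))
        if nights_frames:
            nights = pd.concat(nights_frames, ignore_index=True)
            kept, removed = sleep_activity.filter_nights(nights)
            manifest["filters"]["sleep_nights"] = {
                "in": int(len(nights)), "kept": int(len(kept)),
                "removed": {k: int(v) for k, v in removed.items()},
            }
            save(kept, "sleep_nights.csv")
    except Exception as exc:
        logger.exception("sleep stage failed")
        manifest["failures"].append(f"sleep: {exc}")

    # --- adherence -----------------------------------------------------------
    try:
        series, rates = adherence.adherence_series(phq9, registry, cfg.period_days)
        save(series, "adherence.csv")
        save(rates, "adherence_rates.csv")
        curves = []
        for grp, g in series.groupby("group"):
            c = adherence.km_estimate(g["survival_time"], g["event"])
            c.insert(0, "group", grp)
            curves.append(c)
        save(pd.concat(curves, ignore_index=True), "survival_curves.csv")
        if series["group"].nunique() >= 2:
            stat, p = adherence.logrank_test(
                {g: (gg["survival_time"].to_numpy(), gg["event"].to_numpy())
                 for g, gg in series.groupby("group")}
            )
            manifest["logrank"] = {"statistic": stat, "p_value": p}
        if "battery" in streams:
            per, grp_means = adherence.battery_missingness(streams["battery"], registry)
            save(per, "missingness.csv")
            save(grp_means, "missingness_by_group.csv")
    except Exception as exc:
        logger.exception("adherence stage failed")
        manifest["failures"].append(f"adherence: {exc}")

    # --- association (mixed models) ------------------------------------------
    try:
        daily_parts = []
        if "call" in trimmed:
            hc = preprocess.hourly_counts(trimmed["call"], "call_type", "call_duration")
            dd = _daily_durations(hc, "call_type")
            dd = dd.rename(columns={"incoming": "incoming_call_duration",
                                    "outgoing": "outgoing_call_duration"})
            daily_parts.append(dd[[c for c in dd.columns if c != "missed"]])
        if "sms" in trimmed:
            hs = preprocess.hourly_counts(trimmed["sms"], "message_type")
            ds = (
                hs.groupby(["participant_id", "local_date", "message_type"], observed=True)["count"]
                .sum().unstack("message_type").reset_index()
            )
            ds.columns.name = None
            ds = ds.rename(columns={"incoming": "n_incoming_sms", "outgoing": "n_outgoing_sms"})
            daily_parts.append(ds)
        if "app" in restricted:
            ha = preprocess.hourly_counts(restricted["app"], "category", "duration")
            da = _daily_durations(ha, "category")
            da = da.rename(columns={"social media": "social_media", "communication": "communication_app"})
            keep = ["participant_id", "local_date", "social_media", "communication_app", "games", "leisure"]
            daily_parts.append(da[[c for c in keep if c in da.columns]])
        if "screen" in trimmed:
            sessions = preprocess.screen_sessions(trimmed["screen"])
            if not sessions.empty:
                sessions = data_model.localize(sessions, cfg.timezone)
                dscr = (
                    sessions.groupby(["participant_id", "local_date"])["duration"].sum() / 60.0
                ).rename("screen_use").reset_index()
                daily_parts.append(dscr)
        if "accelerometer" in trimmed:
            sd = preprocess.accel_magnitude_sd(trimmed["accelerometer"])
            daily_parts.append(association.day_part_accel_features(sd))
        if not mob_daily.empty:
            daily_parts.append(mob_daily.drop(columns=["is_weekday", "entropy"]))
        if daily_parts:
            daily = daily_parts[0]
            for part in daily_parts[1:]:
                daily = daily.merge(part, on=["participant_id", "local_date"], how="outer")
            windows = association.center_within_person(
                association.build_windows(daily, phq9, cfg.window_days)
            )
            save(windows, "windows.csv")
            results = []
            for name, spec in association.MODEL_SPECS.items():
                if not all(c in windows.columns for c in spec):
                    continue
                try:
                    res = association.fit_lmm(windows, spec, model_name=name)
                except ValueError as exc:  # insufficient data for this domain
                    manifest["skipped"].append(f"lmm_{name}: {exc}")
                    continue
                tab = res.summary().reset_index()
                tab.insert(0, "model", name)
                tab["intercept_sd"] = res.intercept_sd
                tab["residual_sd"] = res.residual_sd
                tab["n_obs"] = res.n_obs
                tab["n_participants"] = res.n_participants
                results.append(tab)
            if results:
                save(pd.concat(results, ignore_index=True), "lmm_results.csv")
    except Exception as exc:
        logger.exception("association stage failed")
        manifest["failures"].append(f"association: {exc}")

    import lifelines as _ll
    import sklearn as _sk
    import statsmodels as _sm

    manifest["versions"] = {
        "momopheno": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": _sm.__version__,
        "lifelines": _ll.__version__,
        "scikit-learn": _sk.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
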