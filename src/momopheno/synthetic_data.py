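"""Synthetic multimodal passive-sensing cohort generator.

The study population this generator emulates is a clinical digital-phenotyping
cohort: healthy controls plus three patient subcohorts in a major depressive
episode (MDD, BD, BPD), each carrying a smartphone that logs calls, SMS,
screen events, foreground app sessions, GPS fixes, accelerometer samples and
battery pings, plus a two-week "active phase" with a wrist actigraph (30-s
epochs) and a bed-occupancy sensor (1-s epochs).  Participants answer a
PHQ-9 every 14 days and leave the study at group-dependent rates.

Structure planted in the streams (all configurable through
:class:`PlantedEffects`):

* hour-of-week event-intensity templates per group drive an inhomogeneous
  Poisson process for calls/SMS/screen/app events (weekly rhythms);
* per-group anchor-place mixtures (home/work/other) drive GPS fixes, so
  mobility features differ by group;
* group-dependent geometric dropout over 14-day periods;
* group-dependent probability of fully missing passive-data days (battery);
* true mixed-model coefficients linking 14-day feature means to PHQ-9.

One master seed; per-participant per-sensor sub-seeds are derived by a
stable hash so regenerating one sensor never perturbs another.
Timestamps are generated on the local clock of the configured zone and
stored as UTC instants plus the zone name.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SENSOR_PAYLOADS, concat_streams

GROUPS = ("control", "mdd", "bd", "bpd")

#: Week-8 adherence fractions reported per group; the per-period geometric
#: dropout hazard h solves (1-h)^4 = adherence at week 8 (4 biweekly periods).
_WEEK8_ADHERENCE = {"control": 0.52, "mdd": 0.739, "bd": 0.833, "bpd": 0.50}

#: Group mean baseline PHQ-9 scores.
_BASELINE_PHQ9 = {"control": 1.7, "mdd": 14.6, "bd": 13.53, "bpd": 14.57}

#: Fraction of enrolled days with no passive data at all, per group.
_MISSING_DAY_PROB = {"control": 0.012, "mdd": 0.141, "bd": 0.045, "bpd": 0.204}

_STUDY_START = pd.Timestamp("2019-01-07")  # a Monday

#: Small foreground-app catalog; unknown apps map to "uncategorized" downstream.
APP_CATALOG: dict[str, str] = {
    "whatsapp": "communication",
    "telegram": "communication",
    "gmail": "communication",
    "instagram": "social media",
    "facebook": "social media",
    "youtube": "leisure",
    "netflix": "leisure",
    "spotify": "leisure",
    "wordfeud": "games",
    "candycrush": "games",
    "hs_news": "news",
    "yle_news": "news",
    "maps": "transport",
    "hsl": "transport",
    "sbank": "utility",
    "calendar": "work",
    "slack": "work",
    "sportstracker": "sports",
    "verkkokauppa": "shop",
}


def _subseed(master: int, *parts: object) -> int:
    """Stable sub-seed < 2^31 from a master seed and arbitrary labels."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master)).encode())
    for p in parts:
        h.update(b"\x00" + str(p).encode())
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def diurnal_template(
    peaks: Sequence[float] = (9.0, 18.0),
    widths: Sequence[float] = (2.5, 3.0),
    amplitudes: Sequence[float] | None = None,
    night_floor: float = 0.05,
    weekend_factor: float = 0.8,
) -> np.ndarray:
    """Smooth non-negative 168-vector hour-of-week intensity template.

    Sum of Gaussian bumps over the 24-h clock plus a floor, repeated over the
    week with Saturday/Sunday scaled by ``weekend_factor``; normalized to
    mean 1 so it rescales a daily base rate without changing total volume.
    """
    hours = np.arange(24, dtype=float)
    if amplitudes is None:
        amplitudes = [1.0] * len(peaks)
    day = np.full(24, night_floor)
    for p, w, a in zip(peaks, widths, amplitudes):
        day = day + a * np.exp(-0.5 * ((hours - p) / w) ** 2)
    week = np.concatenate([day] * 7)
    week[5 * 24 :] *= weekend_factor
    return week / week.mean()


def default_rhythm_templates(groups: Iterable[str] = GROUPS) -> dict[str, np.ndarray]:
    """Per-group event-intensity templates.

    Controls peak in the afternoon with a marked weekend dip (typical for an
    employed population); patient groups are shifted toward late morning with
    flatter weekends.
    """
    presets = {
        "control": diurnal_template(peaks=(14.0, 19.0), widths=(3.0, 2.0), weekend_factor=0.7),
        "mdd": diurnal_template(peaks=(11.0, 20.0), widths=(3.5, 2.5), weekend_factor=0.95),
        "bd": diurnal_template(peaks=(11.5, 20.5), widths=(3.5, 2.5), weekend_factor=0.95),
        "bpd": diurnal_template(peaks=(12.0, 21.0), widths=(3.5, 2.5), weekend_factor=0.95),
    }
    return {g: presets[g] for g in groups}


def default_mobility_profiles(groups: Iterable[str] = GROUPS) -> dict[str, dict]:
    """Anchor-place mixture per group: patients spend more time at home."""
    out = {}
    for g in groups:
        if g == "control":
            out[g] = {"p_work": 0.8, "p_other": 0.35, "work_km": 4.0, "other_km": 1.5,
                      "jitter_m": 25.0}
        else:
            out[g] = {"p_work": 0.15, "p_other": 0.15, "work_km": 2.0, "other_km": 0.8,
                      "jitter_m": 25.0}
    return out


@dataclass
class CohortConfig:
    """Study design: group sizes, length, timezone and master seed."""

    n_per_group: Mapping[str, int] | int
    group_labels: tuple[str, ...] = GROUPS
    study_days: int = 365
    timezone: str = "Europe/Helsinki"
    seed: int = 0
    enroll_span_days: int = 90
    active_phase_days: int = 14
    actigraph_noise: float = 0.02
    sleep_jitter_min: float = 30.0
    sleep_hours: tuple[float, float] = (23.0, 7.0)  # scheduled bedtime, waketime
    daily_rates: Mapping[str, float] = field(
        default_factory=lambda: {"call": 2.5, "sms": 2.5, "screen": 45.0, "app": 30.0}
    )

    def __post_init__(self) -> None:
        unknown = set(self.group_labels) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}; allowed {GROUPS}")
        if isinstance(self.n_per_group, int):
            if self.n_per_group < 1:
                raise ValueError("n_per_group must be >= 1")
            self.n_per_group = {g: self.n_per_group for g in self.group_labels}
        else:
            self.n_per_group = dict(self.n_per_group)
            bad = set(self.n_per_group) - set(self.group_labels)
            if bad:
                raise ValueError(f"n_per_group has labels not in group_labels: {sorted(bad)}")
            if any(n < 1 for n in self.n_per_group.values()):
                raise ValueError("all group counts must be >= 1")
        if self.study_days < 28:
            raise ValueError("study_days must be >= 28")


@dataclass
class PlantedEffects:
    """Ground truth planted in the synthetic streams, for recovery tests."""

    rhythm_templates: dict[str, np.ndarray] = field(default_factory=default_rhythm_templates)
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "incoming_call_duration": -0.08,
            "outgoing_call_duration": 0.05,
            "magnitude_sd_morning": -2.05,
        }
    )
    random_intercept_sd: float = 2.0
    residual_sd: float = 3.0
    baseline_phq9: dict[str, float] = field(default_factory=lambda: dict(_BASELINE_PHQ9))
    dropout_hazard: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 - a**0.25 for g, a in _WEEK8_ADHERENCE.items()}
    )
    missing_day_prob: dict[str, float] = field(default_factory=lambda: dict(_MISSING_DAY_PROB))
    mobility_profiles: dict[str, dict] = field(default_factory=default_mobility_profiles)
    rhythm_noise_sd: float = 0.3
    activity_factor_sd: float = 0.25  # log-normal SD of the per-person event-rate multiplier

    def __post_init__(self) -> None:
        for g, t in self.rhythm_templates.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (168,) or (t < 0).any():
                raise ValueError(f"rhythm template for {g!r} must be a non-negative 168-vector")
            self.rhythm_templates[g] = t
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for g, h in self.dropout_hazard.items():
            if not 0 <= h < 1:
                raise ValueError(f"dropout_hazard[{g!r}] must lie in [0, 1)")


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    age: float
    sex: str
    employment: str
    enroll_date: pd.Timestamp
    exit_date: pd.Timestamp


def generate_cohort(config: CohortConfig, effects: PlantedEffects | None = None) -> list[ParticipantRecord]:
    """Draw the participant registry: demographics, rolling enrollment, dropout.

    Exit dates follow a geometric process on 14-day period boundaries with
    the per-group hazard, capped at ``study_days`` after enrollment.
    """
    effects = effects or PlantedEffects()
    missing = set(config.group_labels) - set(effects.dropout_hazard)
    if missing:
        raise ValueError(f"dropout_hazard missing groups {sorted(missing)}")
    rng = np.random.default_rng(_subseed(config.seed, "cohort"))
    records: list[ParticipantRecord] = []
    i = 0
    for group in config.group_labels:
        n = config.n_per_group[group]
        hazard = effects.dropout_hazard[group]
        for _ in range(n):
            pid = f"p{i:04d}"
            i += 1
            if group == "control":
                age = float(np.clip(rng.normal(42.0, 14.07), 18, 75))
                p_female, p_fulltime = 0.77, 0.83
            else:
                age = float(np.clip(rng.normal(34.7, 12.71), 18, 75))
                p_female, p_fulltime = 0.711, 0.099
            sex = "female" if rng.random() < p_female else "male"
            employment = "full_time" if rng.random() < p_fulltime else "other"
            enroll = _STUDY_START + pd.Timedelta(days=int(rng.integers(0, config.enroll_span_days + 1)))
            if hazard > 0:
                k = int(rng.geometric(hazard))  # periods completed before leaving
                exit_days = min(14 * k, config.study_days)
            else:
                exit_days = config.study_days
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    group=group,
                    age=round(age, 1),
                    sex=sex,
                    employment=employment,
                    enroll_date=enroll,
                    exit_date=enroll + pd.Timedelta(days=exit_days),
                )
            )
    return records


def cohort_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Registry as a DataFrame (one row per participant)."""
    return pd.DataFrame([r.__dict__ for r in cohort])


# ---------------------------------------------------------------------------
# Event streams
# ---------------------------------------------------------------------------

def _local_grid(rec: ParticipantRecord, tz: str, freq: str,
                end: pd.Timestamp | None = None) -> pd.DatetimeIndex:
    start = rec.enroll_date.tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
    stop = (end if end is not None else rec.exit_date).tz_localize(
        tz, nonexistent="shift_forward", ambiguous=True
    )
    return pd.date_range(start, stop, freq=freq, inclusive="left")


def _poisson_event_times(rng: np.random.Generator, hours: pd.DatetimeIndex,
                         rate_per_hour: np.ndarray) -> pd.DatetimeIndex:
    counts = rng.poisson(rate_per_hour)
    starts = np.repeat(hours.asi8, counts)
    offsets = (rng.random(starts.size) * 3600e9).astype("int64")
    times = pd.DatetimeIndex(starts + offsets, tz=hours.tz).sort_values()
    return times


def _personal_template(rng: np.random.Generator, group_template: np.ndarray,
                       noise_sd: float) -> np.ndarray:
    t = group_template * rng.lognormal(0.0, noise_sd, size=168)
    return t / t.mean()


def _base(rec: ParticipantRecord, times: pd.DatetimeIndex, tz: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": rec.participant_id,
            "device_id": f"dev-{rec.participant_id}",
            "timestamp_utc": times.tz_convert("UTC"),
            "tz": tz,
        }
    )


def _gen_point_events(rng, rec, effects, config, sensor) -> pd.DataFrame:
    tz = config.timezone
    hours = _local_grid(rec, tz, "h")
    how = hours.weekday * 24 + hours.hour
    template = _personal_template(rng, effects.rhythm_templates[rec.group],
                                  effects.rhythm_noise_sd)
    person_factor = rng.lognormal(0.0, effects.activity_factor_sd) if effects.activity_factor_sd else 1.0
    rate = config.daily_rates[sensor] / 24.0 * template[how] * person_factor
    times = _poisson_event_times(rng, hours, rate)
    df = _base(rec, times, tz)
    n = len(df)
    if sensor == "call":
        call_type = rng.choice(["incoming", "outgoing", "missed"], size=n, p=[0.42, 0.43, 0.15])
        duration = np.round(rng.lognormal(4.0, 1.3, size=n), 0)
        duration[call_type == "missed"] = 0.0
        df["call_type"] = call_type
        df["call_duration"] = duration
    elif sensor == "sms":
        df["message_type"] = rng.choice(["incoming", "outgoing"], size=n)
    elif sensor == "screen":
        # one use episode per session: on..off or unlock..lock, 50/50
        dur = np.minimum(rng.lognormal(math.log(90.0), 1.0, size=n), 7200.0)
        kind = rng.random(n) < 0.5
        start = pd.DatetimeIndex(df["timestamp_utc"])
        end = start + pd.to_timedelta(dur, unit="s")
        rows = pd.DataFrame(
            {
                "participant_id": rec.participant_id,
                "device_id": f"dev-{rec.participant_id}",
                "timestamp_utc": start.append(end),
                "tz": tz,
                "screen_status": np.concatenate(
                    [np.where(kind, "on", "unlock"), np.where(kind, "off", "lock")]
                ),
            }
        )
        df = rows
    elif sensor == "app":
        names = list(APP_CATALOG)
        df["application_name"] = rng.choice(names, size=n)
        dur = rng.lognormal(math.log(180.0), 1.1, size=n)
        long = rng.random(n) < 0.002  # rare implausible marathon sessions
        dur[long] = rng.uniform(10.2 * 3600, 12 * 3600, size=int(long.sum()))
        df["duration"] = np.round(dur, 1)
    return df


def _gen_location(rng, rec, effects, config) -> pd.DataFrame:
    tz = config.timezone
    prof = effects.mobility_profiles[rec.group]
    bins = _local_grid(rec, tz, "10min")
    home = np.array([60.17 + rng.normal(0, 0.03), 24.94 + rng.normal(0, 0.05)])
    km_lat = 1 / 110.574
    km_lon = 1 / (111.320 * math.cos(math.radians(home[0])))
    theta = rng.uniform(0, 2 * math.pi)
    work = home + prof["work_km"] * np.array([math.cos(theta) * km_lat, math.sin(theta) * km_lon])
    phi = rng.uniform(0, 2 * math.pi)
    other = home + prof["other_km"] * np.array([math.cos(phi) * km_lat, math.sin(phi) * km_lon])
    hour = bins.hour.to_numpy()
    wd = bins.weekday.to_numpy()
    u = rng.random(len(bins))
    at_work = (wd < 5) & (hour >= 9) & (hour < 17) & (u < prof["p_work"])
    at_other = ~at_work & (hour >= 17) & (hour < 21) & (u < prof["p_other"])
    lat = np.where(at_work, work[0], np.where(at_other, other[0], home[0]))
    lon = np.where(at_work, work[1], np.where(at_other, other[1], home[1]))
    jd_lat = prof["jitter_m"] / 110574.0
    jd_lon = prof["jitter_m"] / (111320.0 * math.cos(math.radians(home[0])))
    lat = lat + rng.normal(0, jd_lat, len(bins))
    lon = lon + rng.normal(0, jd_lon, len(bins))
    df = _base(rec, bins, tz)
    df["latitude"] = np.round(lat, 6)
    df["longitude"] = np.round(lon, 6)
    df["speed"] = np.round(np.abs(rng.normal(0, 0.3, len(bins))), 2)
    acc = rng.lognormal(math.log(20.0), 0.5, len(bins))
    poor = rng.random(len(bins)) < 0.02
    acc[poor] *= 10.0
    df["accuracy"] = np.round(acc, 1)
    return df


_ACCEL_SD_BY_HOUR = {"night": 0.05, "morning": 0.55, "afternoon": 0.6, "evening": 0.45}


def _gen_accelerometer(rng, rec, effects, config) -> pd.DataFrame:
    tz = config.timezone
    grid = _local_grid(rec, tz, "30s")
    hour = grid.hour.to_numpy()
    sd = np.select(
        [hour < 6, hour < 12, hour < 18],
        [_ACCEL_SD_BY_HOUR["night"], _ACCEL_SD_BY_HOUR["morning"], _ACCEL_SD_BY_HOUR["afternoon"]],
        default=_ACCEL_SD_BY_HOUR["evening"],
    )
    scale = rng.lognormal(0.0, 0.15)
    x = 1.0 + rng.normal(0.0, sd * scale, len(grid))
    df = _base(rec, grid, tz)
    df["x"] = np.round(x, 4)
    df["y"] = 0.0
    df["z"] = 0.0
    return df


def _sleep_schedule(rng, rec, config) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Per-night (bedtime, waketime) local instants for the active phase."""
    tz = config.timezone
    bed_h, wake_h = config.sleep_hours
    jitter = config.sleep_jitter_min
    nights = []
    for d in range(config.active_phase_days):
        date = rec.enroll_date + pd.Timedelta(days=d)
        bed = (date + pd.Timedelta(hours=bed_h)
               + pd.Timedelta(minutes=float(rng.normal(0, jitter)) if jitter else 0.0)
               ).tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
        wake = (date + pd.Timedelta(days=1 if wake_h <= bed_h else 0, hours=wake_h)
                + pd.Timedelta(minutes=float(rng.normal(0, jitter)) if jitter else 0.0)
                ).tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
        nights.append((bed, wake))
    return nights


def planted_sleep_schedule(
    rec: ParticipantRecord, config: CohortConfig
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Ground-truth (bedtime, waketime) per active-phase night for ``rec``.

    Reproduces exactly the schedule the actigraph and bed generators used,
    for sleep-scoring recovery tests.
    """
    rng = np.random.default_rng(_subseed(config.seed, rec.participant_id, "sleep_schedule"))
    return _sleep_schedule(rng, rec, config)


def _gen_actigraph(rng, rec, effects, config) -> pd.DataFrame:
    tz = config.timezone
    end = rec.enroll_date + pd.Timedelta(days=config.active_phase_days + 1)
    end = min(end, rec.exit_date)
    grid = _local_grid(rec, tz, "30s", end=end)
    status = np.full(len(grid), "active", dtype=object)
    t = grid.asi8
    sched_rng = np.random.default_rng(_subseed(config.seed, rec.participant_id, "sleep_schedule"))
    for bed, wake in _sleep_schedule(sched_rng, rec, config):
        b, w = bed.value, wake.value
        status[(t >= b - 30 * 60 * 10**9) & (t < b)] = "rest"
        status[(t >= b) & (t < w)] = "sleep"
        status[(t >= w) & (t < w + 15 * 60 * 10**9)] = "rest"
    noise = rng.random(len(grid)) < config.actigraph_noise
    flips = rng.choice(["active", "rest", "sleep"], size=int(noise.sum()))
    status[noise] = flips
    counts = np.where(status == "active", rng.poisson(150, len(grid)),
                      np.where(status == "rest", rng.poisson(20, len(grid)), rng.poisson(2, len(grid))))
    df = _base(rec, grid, tz)
    df["activity_count"] = counts
    df["status"] = status
    return df


def _gen_bed(rng, rec, effects, config) -> pd.DataFrame:
    tz = config.timezone
    frames = []
    sched_rng = np.random.default_rng(_subseed(config.seed, rec.participant_id, "sleep_schedule"))
    for bed, wake in _sleep_schedule(sched_rng, rec, config):
        start = bed - pd.Timedelta(minutes=45)
        stop = wake + pd.Timedelta(minutes=45)
        grid = pd.date_range(start, stop, freq="1s", inclusive="left")
        occ = np.where(
            (grid >= bed - pd.Timedelta(minutes=15)) & (grid < wake + pd.Timedelta(minutes=10)),
            "occupied", "free",
        ).astype(object)
        if rng.random() < 0.3:  # brief nocturnal absence
            gap_start = bed + pd.Timedelta(hours=float(rng.uniform(1, 5)))
            gap = (grid >= gap_start) & (grid < gap_start + pd.Timedelta(minutes=float(rng.uniform(1, 5))))
            occ[gap] = "free"
        f = _base(rec, grid, tz)
        f["occupancy"] = occ
        frames.append(f)
    if not frames:
        cols = ["participant_id", "device_id", "timestamp_utc", "tz", "occupancy"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def _gen_battery(rng, rec, effects, config) -> pd.DataFrame:
    tz = config.timezone
    days = pd.date_range(rec.enroll_date, rec.exit_date, freq="D", inclusive="left")
    p_miss = effects.missing_day_prob.get(rec.group, 0.0)
    keep = rng.random(len(days)) >= p_miss
    times, levels = [], []
    for day in days[keep]:
        for h in range(0, 24, 4):
            ts = (day + pd.Timedelta(hours=h, minutes=float(rng.uniform(0, 30)))
                  ).tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
            times.append(ts)
            levels.append(int(np.clip(100 - h * 3 + rng.normal(0, 5), 5, 100)))
    idx = pd.DatetimeIndex(times)
    df = _base(rec, idx if len(idx) else pd.DatetimeIndex([], tz="UTC"), tz)
    df["battery_level"] = levels
    df["battery_status"] = "discharging"
    return df


_SENSOR_GENERATORS = {
    "call": _gen_point_events,
    "sms": _gen_point_events,
    "screen": _gen_point_events,
    "app": _gen_point_events,
    "location": _gen_location,
    "accelerometer": _gen_accelerometer,
    "actigraph": _gen_actigraph,
    "bed": _gen_bed,
    "battery": _gen_battery,
}


def generate_event_streams(
    cohort: Sequence[ParticipantRecord],
    effects: PlantedEffects,
    config: CohortConfig,
    sensors: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate all (or selected) sensor streams for a cohort.

    Every event falls inside the participant's enrollment window; output
    is deterministic given the config seed.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    sensors = list(sensors) if sensors is not None else list(_SENSOR_GENERATORS)
    streams: dict[str, pd.DataFrame] = {}
    for sensor in sensors:
        gen = _SENSOR_GENERATORS[sensor]
        frames = []
        for rec in cohort:
            rng = np.random.default_rng(_subseed(config.seed, rec.participant_id, sensor))
            if gen is _gen_point_events:
                frames.append(gen(rng, rec, effects, config, sensor))
            else:
                frames.append(gen(rng, rec, effects, config))
        df = concat_streams(frames)
        cols = ["participant_id", "device_id", "timestamp_utc", "tz"] + SENSOR_PAYLOADS[sensor]
        streams[sensor] = df.loc[:, cols]
    return streams


# ---------------------------------------------------------------------------
# PHQ-9
# ---------------------------------------------------------------------------

def generate_phq9(
    cohort: Sequence[ParticipantRecord],
    effects: PlantedEffects,
    daily_features: pd.DataFrame | None = None,
    config: CohortConfig | None = None,
    window_days: int = 14,
    response_missing_prob: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Biweekly PHQ-9 responses with planted feature effects.

    ``daily_features`` (optional): columns ``participant_id``, ``local_date``
    plus one column per predictor named in ``effects.beta``.  Each response's
    score is

        clip(round(baseline_g + sum_k beta_k * centered_feature_k
                   + intercept_i + noise), 0, 27)

    where features are the means over the 14 local dates preceding the
    response date, centered within person.  Windows with no feature data are
    generated from baseline only and flagged (``features_missing``).
    """
    seed = seed if seed is not None else (config.seed if config is not None else 0)
    rows = []
    feat_cols = list(effects.beta)
    by_pid: dict[str, pd.DataFrame] = {}
    if daily_features is not None:
        for pid, g in daily_features.groupby("participant_id"):
            by_pid[pid] = g.set_index(pd.to_datetime(g["local_date"]))
    for rec in cohort:
        rng = np.random.default_rng(_subseed(seed, rec.participant_id, "phq9"))
        intercept = rng.normal(0.0, effects.random_intercept_sd)
        baseline = effects.baseline_phq9[rec.group]
        n_periods = int((rec.exit_date - rec.enroll_date).days // window_days)
        # raw window means first, then within-person centering
        per_resp = []
        for k in range(n_periods + 1):
            resp_date = rec.enroll_date + pd.Timedelta(days=window_days * k)
            if resp_date > rec.exit_date:
                break
            if k > 0 and rng.random() < response_missing_prob:
                continue  # intermittent missing response
            means = {}
            if rec.participant_id in by_pid and k > 0:
                g = by_pid[rec.participant_id]
                lo = resp_date - pd.Timedelta(days=window_days)
                win = g[(g.index >= lo) & (g.index < resp_date)]
                for c in feat_cols:
                    if c in win.columns and win[c].notna().any():
                        means[c] = float(win[c].mean())
            per_resp.append((k, resp_date, means))
        if not per_resp:
            continue
        person_means = {
            c: np.mean([m[c] for _, _, m in per_resp if c in m])
            for c in feat_cols
            if any(c in m for _, _, m in per_resp)
        }
        for k, resp_date, means in per_resp:
            effect = 0.0
            missing = len(means) < len(feat_cols)
            for c, v in means.items():
                effect += effects.beta[c] * (v - person_means[c])
            noise = rng.normal(0.0, effects.residual_sd)
            score = int(np.clip(round(baseline + effect + intercept + noise), 0, 27))
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "response_date": resp_date,
                    "score": score,
                    "period_index": k,
                    "features_missing": bool(missing and daily_features is not None),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Direct simulators for recovery studies
# ---------------------------------------------------------------------------

def simulate_association_windows(
    n_participants: int = 100,
    n_windows: int = 12,
    beta: Mapping[str, float] | None = None,
    random_intercept_sd: float = 2.0,
    residual_sd: float = 3.0,
    baseline: float = 10.0,
    within_sd: Mapping[str, float] | None = None,
    between_sd: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Window-level dataset for mixed-model parameter recovery.

    Predictor defaults mirror the planted effect sizes (call durations in
    minutes, accelerometer magnitude SD in g): within-person SDs of 5 min for
    durations and 0.2 for the accelerometer feature.
    Returns ``(windows, truth)`` where windows has raw predictor columns and
    ``phq9``.
    """
    beta = dict(beta) if beta is not None else {
        "incoming_call_duration": -0.08,
        "outgoing_call_duration": 0.05,
        "magnitude_sd_morning": -2.05,
    }
    default_scale = {"incoming_call_duration": (8.0, 3.0, 5.0),
                     "outgoing_call_duration": (8.0, 3.0, 5.0),
                     "magnitude_sd_morning": (0.5, 0.15, 0.2)}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"p{i:04d}"
        b_i = rng.normal(0.0, random_intercept_sd)
        mus = {}
        for c in beta:
            loc, bsd, _ = default_scale.get(c, (0.0, 1.0, 1.0))
            bsd = between_sd[c] if between_sd and c in between_sd else bsd
            mus[c] = rng.normal(loc, bsd)
        for w in range(n_windows):
            row = {"participant_id": pid, "window": w}
            effect = 0.0
            for c, b in beta.items():
                _, _, wsd = default_scale.get(c, (0.0, 1.0, 1.0))
                wsd = within_sd[c] if within_sd and c in within_sd else wsd
                dev = rng.normal(0.0, wsd)
                row[c] = mus[c] + dev
                effect += b * dev
            row["phq9"] = baseline + effect + b_i + rng.normal(0.0, residual_sd)
            rows.append(row)
    truth = {"beta": beta, "random_intercept_sd": random_intercept_sd,
             "residual_sd": residual_sd, "baseline": baseline}
    return pd.DataFrame(rows), truth


def simulate_rhythm_cohort(
    n_per_group: Mapping[str, int] | None = None,
    patient_noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Weekly-rhythm weight vectors with a homogeneous patient group.

    Patients share one rhythm template perturbed by multiplicative log-normal
    noise; each control gets an independently drawn template (random peak
    hours, widths and weekend factor), making the control group's pairwise
    cosine distances systematically larger.  Returns a frame with
    ``participant_id``, ``group`` and weight columns ``w000``..``w167``
    (each row sums to 1).
    """
    n_per_group = dict(n_per_group) if n_per_group else {"patient": 30, "control": 30}
    rng = np.random.default_rng(seed)
    shared = diurnal_template(peaks=(10.0, 20.0), widths=(3.0, 2.5), weekend_factor=0.9)
    rows = []
    i = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            if group == "patient":
                t = shared * rng.lognormal(0.0, patient_noise_sd, 168)
            else:
                t = diurnal_template(
                    peaks=tuple(rng.uniform(6, 23, 2)),
                    widths=tuple(rng.uniform(1.0, 5.0, 2)),
                    amplitudes=tuple(rng.uniform(0.5, 2.0, 2)),
                    weekend_factor=float(rng.uniform(0.3, 1.6)),
                ) * rng.lognormal(0.0, patient_noise_sd, 168)
            w = t / t.sum()
            rows.append({"participant_id": f"r{i:04d}", "group": group,
                         **{f"w{k:03d}": w[k] for k in range(168)}})
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_truth(effects: PlantedEffects, path: str | Path) -> None:
    """Record the planted ground truth alongside a simulated dataset."""
    payload = {
        "beta": effects.beta,
        "random_intercept_sd": effects.random_intercept_sd,
        "residual_sd": effects.residual_sd,
        "baseline_phq9": effects.baseline_phq9,
        "dropout_hazard": effects.dropout_hazard,
        "missing_day_prob": effects.missing_day_prob,
        "rhythm_templates": {g: t.tolist() for g, t in effects.rhythm_templates.items()},
        "mobility_profiles": effects.mobility_profiles,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_streams(
    streams: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    formats: Sequence[str] = ("csv", "parquet"),
) -> list[Path]:
    """One file per sensor per format under ``outdir``."""
    from .data_model import write_events

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sensor, df in streams.items():
        for fmt in formats:
            p = outdir / f"{sensor}.{fmt}"
            write_events(df, p)
            written.append(p)
    return written
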