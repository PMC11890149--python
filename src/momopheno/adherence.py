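"""Study adherence: PHQ-9 availability, survival curves, data missingness.

Adherence is defined by the availability of biweekly PHQ-9 responses: a
participant is active in 14-day period k if they answered at least one
PHQ-9 in that period.  Intermittent gaps do not terminate participation —
survival time runs to the last period with a response.  A participant whose
last response precedes their final possible period is a dropout event at
the period after that response; one who responds in the final period is
administratively censored.

Passive-data completeness uses battery pings as the proxy: a study day with
no battery rows at all counts as a missing day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


def adherence_series(
    phq9: pd.DataFrame, registry: pd.DataFrame, period_days: int = 14
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant survival data and per-period group adherence rates.

    ``registry`` needs participant_id, group, enroll_date and (optionally)
    exit_date or a study length implying the number of periods available.
    Returns ``(series, rates)``: one row per participant with
    ``survival_time`` (periods until last response) and ``event`` (1 =
    dropout, 0 = censored), and a per period x group rate table
    (responders / enrolled).
    """
    reg = registry.copy()
    reg["enroll_date"] = pd.to_datetime(reg["enroll_date"])
    if "exit_date" in reg.columns:
        reg["exit_date"] = pd.to_datetime(reg["exit_date"])
        reg["n_periods"] = ((reg["exit_date"] - reg["enroll_date"]).dt.days // period_days).astype(int)
    else:
        reg["n_periods"] = phq9["period_index"].max()
    responded: dict[str, set[int]] = {pid: set() for pid in reg["participant_id"]}
    for _, r in phq9.iterrows():
        responded.setdefault(r["participant_id"], set()).add(int(r["period_index"]))
    rows = []
    for _, r in reg.iterrows():
        pid = r["participant_id"]
        periods = responded.get(pid, set())
        last = max(periods) if periods else -1
        survival = max(last, 0)
        event = 1 if last < r["n_periods"] else 0
        rows.append(
            {
                "participant_id": pid,
                "group": r["group"],
                "n_periods": int(r["n_periods"]),
                "last_response_period": last,
                "survival_time": int(survival),
                "event": int(event),
            }
        )
    series = pd.DataFrame(rows)
    max_period = int(reg["n_periods"].max())
    rate_rows = []
    for k in range(0, max_period + 1):
        enrolled = reg[reg["n_periods"] >= k]
        for grp, g in enrolled.groupby("group"):
            n_resp = sum(1 for pid in g["participant_id"] if k in responded.get(pid, set()))
            rate_rows.append(
                {
                    "period_index": k,
                    "group": grp,
                    "n_enrolled": len(g),
                    "n_responded": n_resp,
                    "rate": n_resp / len(g) if len(g) else np.nan,
                }
            )
    return series, pd.DataFrame(rate_rows)


def km_estimate(durations, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a step table with event times, S(t) and at-risk counts.  With
    no censoring this equals the empirical survival function.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if (durations < 0).any():
        raise ValueError("durations must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.to_numpy(),
        }
    )


def logrank_test(groups: dict[str, tuple]) -> tuple[float, float]:
    """k-group log-rank test; ``groups`` maps label -> (durations, events).

    Returns (chi-square statistic with k-1 df, P value).
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    durs, evs, labels = [], [], []
    for label, (d, e) in groups.items():
        d = np.asarray(d, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(d) == 0:
            raise ValueError(f"group {label!r} is empty")
        durs.append(d)
        evs.append(e)
        labels.extend([label] * len(d))
    res = multivariate_logrank_test(
        np.concatenate(durs), np.array(labels), np.concatenate(evs)
    )
    return float(res.test_statistic), float(res.p_value)


def battery_missingness(
    battery: pd.DataFrame, registry: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of enrolled days with no battery data, per participant & group.

    A day counts as missing if the participant has zero battery rows on that
    local date inside [enroll_date, exit_date).  Returns per-participant
    percentages and per-group means of those percentages.
    """
    reg = registry.copy()
    reg["enroll_date"] = pd.to_datetime(reg["enroll_date"])
    reg["exit_date"] = pd.to_datetime(reg["exit_date"])
    have = battery.groupby("participant_id")["local_date"].apply(set).to_dict()
    rows = []
    for _, r in reg.iterrows():
        days = pd.date_range(r["enroll_date"], r["exit_date"], freq="D", inclusive="left")
        if len(days) == 0:
            rows.append(
                {"participant_id": r["participant_id"], "group": r["group"],
                 "n_days": 0, "pct_missing": np.nan}
            )
            continue
        seen = have.get(r["participant_id"], set())
        n_missing = sum(1 for d in days if d not in seen)
        rows.append(
            {
                "participant_id": r["participant_id"],
                "group": r["group"],
                "n_days": len(days),
                "pct_missing": 100.0 * n_missing / len(days),
            }
        )
    per = pd.DataFrame(rows)
    grp = per.groupby("group")["pct_missing"].mean().rename("mean_pct_missing").reset_index()
    return per, grp
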