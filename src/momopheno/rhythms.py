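"""Weekly activity rhythms and within-group homogeneity statistics.

A *weekly rhythm* is the normalized distribution of an activity's event
volume over the 168 hour-of-week bins (Monday 00:00 = bin 0): aggregate
counts over the 8-week analysis window and divide by the grand total so the
weights sum to 1.

The *intradifference* of a group is the multiset of pairwise cosine
distances

    D(R_i, R_j) = 1 - (R_i . R_j) / (||R_i|| ||R_j||)

between the rhythms of individuals i < j in the same group; smaller
distances mean a more homogeneous group.  Groups are compared by a
Mann-Whitney U test on their distance multisets, with Benjamini-Hochberg
adjustment across the activity types tested together.

The MWU test and the BH step-up procedure are implemented here directly
(the MWU with an exact enumeration path for small samples and a
tie-corrected continuity-corrected normal approximation otherwise);
library implementations serve only as cross-checks in the test suite.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

N_BINS = 168

WEIGHT_COLUMNS = [f"w{k:03d}" for k in range(N_BINS)]

#: Coarse day regions (local-hour ranges) used for figure-style summaries.
DAY_REGIONS = {"night": (0, 6), "morning": (6, 12), "afternoon": (12, 18), "evening": (18, 24)}


def weekly_rhythm(hourly, value: str = "count") -> tuple[np.ndarray, bool]:
    """Normalized 168-bin hour-of-week weight vector for one participant.

    ``hourly`` is either a table with ``hour_of_week`` and a value column,
    or a length-168 array of bin totals.  Returns ``(weights, all_zero)``;
    when the grand total is 0 the weights are all zeros and the flag is set.
    """
    if isinstance(hourly, pd.DataFrame):
        totals = np.zeros(N_BINS)
        grouped = hourly.groupby("hour_of_week")[value].sum()
        totals[grouped.index.to_numpy()] = grouped.to_numpy()
    else:
        totals = np.asarray(hourly, dtype=float)
        if totals.shape != (N_BINS,):
            raise ValueError(f"expected a {N_BINS}-vector, got shape {totals.shape}")
    if (totals < 0).any():
        raise ValueError("bin totals must be non-negative")
    grand = totals.sum()
    if grand == 0:
        return totals, True
    return totals / grand, False


def rhythm_table(hourly: pd.DataFrame, value: str = "count") -> pd.DataFrame:
    """Weekly rhythms for every participant in an hourly-counts table.

    Returns one row per participant with weight columns ``w000``..``w167``
    and an ``all_zero`` flag.
    """
    rows = []
    for pid, g in hourly.groupby("participant_id"):
        w, zero = weekly_rhythm(g, value=value)
        rows.append({"participant_id": pid, "all_zero": zero,
                     **{c: w[k] for k, c in enumerate(WEIGHT_COLUMNS)}})
    return pd.DataFrame(rows, columns=["participant_id", "all_zero", *WEIGHT_COLUMNS])


def cosine_distance(r_i: np.ndarray, r_j: np.ndarray) -> float:
    """1 - cos(angle) between two rhythm vectors; in [0, 1] for non-negative input."""
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    ni, nj = np.linalg.norm(r_i), np.linalg.norm(r_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine distance undefined for an all-zero rhythm")
    d = 1.0 - float(r_i @ r_j) / (ni * nj)
    return float(min(max(d, 0.0), 1.0))


def intragroup_distances(
    rhythms: pd.DataFrame, group_col: str = "group"
) -> dict[str, np.ndarray]:
    """All unordered within-group pairwise cosine distances.

    ``rhythms`` must carry the weight columns and a group column; all-zero
    rhythms are excluded.  Each group must retain >= 2 members.
    """
    out = {}
    df = rhythms
    if "all_zero" in df.columns:
        df = df[~df["all_zero"]]
    for grp, g in df.groupby(group_col):
        w = g[WEIGHT_COLUMNS].to_numpy(dtype=float)
        n = len(w)
        if n < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 usable rhythms")
        norms = np.linalg.norm(w, axis=1)
        gram = (w @ w.T) / np.outer(norms, norms)
        iu = np.triu_indices(n, k=1)
        out[grp] = np.clip(1.0 - gram[iu], 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Tests and multiplicity
# ---------------------------------------------------------------------------

EXACT_MAX_N = 16


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 1/2 #ties, via average ranks."""
    n_x = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2)


def mwu_test(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    For combined sample sizes up to ``exact_max_n`` the P value is exact:
    every assignment of the pooled values to the two samples is enumerated
    and assignments at least as extreme (|U - mn/2| >= observed) are
    counted.  Larger samples use the tie-corrected normal approximation
    with continuity correction.  Returns ``(U, p)`` with U counted for the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    mu = n_x * n_y / 2.0
    u_obs = _u_statistic(x, y)
    if n_x + n_y <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        offset = n_x * (n_x + 1) / 2
        dev_obs = abs(u_obs - mu) - 1e-12  # tolerate float fuzz in ties
        hits = total = 0
        for idx in combinations(range(n_x + n_y), n_x):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        return u_obs, hits / total
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    dev = abs(u_obs - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    return u_obs, float(min(2 * norm.sf(z), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (input order preserved).

    adjusted[i] = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def homogeneity_report(
    rhythms_by_type: Mapping[str, pd.DataFrame],
    group_col: str = "group",
    employment: pd.Series | None = None,
    employed_only: bool = False,
) -> pd.DataFrame:
    """Within-group homogeneity comparison per activity type.

    Each entry of ``rhythms_by_type`` is a rhythm table (weight columns plus
    the group column).  For every type: pairwise within-group cosine
    distances, a two-group MWU test on the distance multisets, and BH
    adjustment across the types tested here.  With ``employed_only`` the
    analysis is restricted to participants flagged full-time in
    ``employment`` (an id -> employment mapping).
    """
    rows = []
    for act_type, rhythms in rhythms_by_type.items():
        df = rhythms
        if employed_only:
            if employment is None:
                raise ValueError("employed_only requires an employment mapping")
            keep = df["participant_id"].map(employment) == "full_time"
            df = df[keep]
        dists = intragroup_distances(df, group_col=group_col)
        if len(dists) != 2:
            raise ValueError(f"{act_type}: expected exactly 2 groups, got {sorted(dists)}")
        (ga, da), (gb, db) = sorted(dists.items())
        u, p = mwu_test(da, db)
        rows.append(
            {
                "activity_type": act_type,
                "group_a": ga,
                "group_b": gb,
                "n_pairs_a": len(da),
                "n_pairs_b": len(db),
                "mean_dist_a": float(np.mean(da)),
                "mean_dist_b": float(np.mean(db)),
                "more_homogeneous": ga if np.mean(da) < np.mean(db) else gb,
                "U": u,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def region_summary(weights: np.ndarray) -> dict[str, float]:
    """Sum rhythm weights over the four daily regions (whole week)."""
    w = np.asarray(weights, dtype=float)
    hours = np.arange(N_BINS) % 24
    return {
        name: float(w[(hours >= lo) & (hours < hi)].sum())
        for name, (lo, hi) in DAY_REGIONS.items()
    }
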