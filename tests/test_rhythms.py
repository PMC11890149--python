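"""Weekly rhythms, cosine intradifference, MWU and BH primitives."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momopheno import rhythms as rh
from tests.conftest import local_events


class TestWeeklyRhythm:
    def test_point_mass_rhythm(self):
        # one call every Monday 09:00-10:00 for 8 weeks
        times = [pd.Timestamp("2019-01-07 09:30") + pd.Timedelta(weeks=w) for w in range(8)]
        from momopheno import preprocess as pp

        hourly = pp.hourly_counts(local_events([str(t) for t in times]))
        w, zero = rh.weekly_rhythm(hourly)
        assert not zero
        assert w[9] == pytest.approx(1.0)
        assert w.sum() == pytest.approx(1.0)

    def test_equal_bins_split_half(self):
        totals = np.zeros(168)
        totals[[10, 20]] = 7
        w, _ = rh.weekly_rhythm(totals)
        assert w[10] == w[20] == pytest.approx(0.5)

    def test_any_nonzero_stream_normalizes(self):
        rng = np.random.default_rng(0)
        w, zero = rh.weekly_rhythm(rng.poisson(3, 168).astype(float))
        assert len(w) == 168 and not zero
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_flagged(self):
        w, zero = rh.weekly_rhythm(np.zeros(168))
        assert zero and w.sum() == 0


class TestCosineDistance:
    def test_identity_zero(self):
        w, _ = rh.weekly_rhythm(np.random.default_rng(1).poisson(5, 168).astype(float))
        assert rh.cosine_distance(w, w) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_point_masses_orthogonal(self):
        a, b = np.zeros(168), np.zeros(168)
        a[0], b[1] = 1, 1
        assert rh.cosine_distance(a, b) == pytest.approx(1.0)

    def test_half_mass_hand_case(self):
        a = np.zeros(168)
        a[[0, 1]] = 0.5
        b = np.zeros(168)
        b[0] = 1.0
        assert rh.cosine_distance(a, b) == pytest.approx(1 - 0.5 / np.sqrt(0.5), abs=1e-4)
        assert rh.cosine_distance(a, b) == pytest.approx(0.2929, abs=1e-4)

    def test_all_zero_operand_rejected(self):
        with pytest.raises(ValueError):
            rh.cosine_distance(np.zeros(168), np.ones(168))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_range_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(168)
        b = rng.random(168)
        d = rh.cosine_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(rh.cosine_distance(b, a))
        assert d == pytest.approx(rh.cosine_distance(3.7 * a, b), abs=1e-12)


class TestIntragroupDistances:
    @staticmethod
    def _table(vectors, groups):
        rows = []
        for i, (v, g) in enumerate(zip(vectors, groups)):
            rows.append({"participant_id": f"p{i}", "group": g, "all_zero": False,
                         **{c: v[k] for k, c in enumerate(rh.WEIGHT_COLUMNS)}})
        return pd.DataFrame(rows)

    def test_pair_count(self):
        rng = np.random.default_rng(2)
        tbl = self._table([rng.random(168) for _ in range(4)], ["g"] * 4)
        d = rh.intragroup_distances(tbl)
        assert len(d["g"]) == 6

    def test_identical_rhythms_zero_distance(self):
        v = np.random.default_rng(3).random(168)
        tbl = self._table([v] * 3, ["g"] * 3)
        assert rh.intragroup_distances(tbl)["g"] == pytest.approx(np.zeros(3), abs=1e-12)

    def test_single_member_group_refused(self):
        v = np.random.default_rng(4).random(168)
        with pytest.raises(ValueError, match="fewer than 2"):
            rh.intragroup_distances(self._table([v], ["g"]))

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(5)
        vecs = [rng.random(168) for _ in range(6)]
        tbl = self._table(vecs, ["g"] * 6)
        got = sorted(rh.intragroup_distances(tbl)["g"])
        want = sorted(
            rh.cosine_distance(vecs[i], vecs[j]) for i, j in combinations(range(6), 2)
        )
        assert got == pytest.approx(want)


def _mwu_brute(x, y):
    """Independent oracle: direct pair counting + full enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    pooled = np.concatenate([x, y])
    n_x = len(x)
    mu = len(x) * len(y) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_x):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        xs, ys = pooled[mask], pooled[~mask]
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / total


class TestMwu:
    def test_separated_samples_exact_p(self):
        u, p = rh.mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = rh.mwu_test(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rh.mwu_test([], [1.0])

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n_x = int(rng.integers(2, 6))
            n_y = int(rng.integers(2, 11 - n_x))
            x = rng.integers(0, 6, n_x).astype(float)  # heavy ties
            y = rng.integers(0, 6, n_y).astype(float)
            u1, p1 = rh.mwu_test(x, y)
            u2, p2 = _mwu_brute(x, y)
            assert u1 == pytest.approx(u2)
            assert p1 == pytest.approx(p2)

    def test_exact_and_normal_paths_agree(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = rh.mwu_test(x, y)
            _, p_norm = rh.mwu_test(x, y, exact_max_n=0)
            assert abs(p_exact - p_norm) <= 0.02

    def test_large_sample_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        u, p = rh.mwu_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.05)


def _bh_brute(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, i in enumerate(order, start=1):
        candidates = [p[j] * m / (list(order).index(j) + 1) for j in order[rank_pos - 1:]]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    def test_hand_step_up(self):
        out = rh.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert out == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert rh.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        assert rh.bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rh.bh_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.random(20)
        assert (rh.bh_adjust(p) >= p - 1e-12).all()

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 12)))
            ours = rh.bh_adjust(p)
            assert ours == pytest.approx(_bh_brute(p))
            assert ours == pytest.approx(multipletests(p, method="fdr_bh")[1])


class TestHomogeneityReport:
    @staticmethod
    def _frame(vectors, groups, pids=None):
        rows = []
        for i, (v, g) in enumerate(zip(vectors, groups)):
            pid = pids[i] if pids else f"p{i}"
            rows.append({"participant_id": pid, "group": g, "all_zero": False,
                         **{c: v[k] for k, c in enumerate(rh.WEIGHT_COLUMNS)}})
        return pd.DataFrame(rows)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(11)
        vecs = [rng.random(168) for _ in range(6)]
        frame = self._frame(vecs + vecs, ["control"] * 6 + ["patient"] * 6)
        rep = rh.homogeneity_report({"call": frame, "sms": frame})
        assert (rep["p_adj"] > 0.05).all()

    def test_planted_homogeneous_patients_flagged(self):
        from momopheno import synthetic_data as sd

        r = sd.simulate_rhythm_cohort(seed=12)
        r = r.assign(all_zero=False)
        rep = rh.homogeneity_report({"call": r})
        assert rep.loc[0, "more_homogeneous"] == "patient"
        assert rep.loc[0, "p_adj"] < 0.05

    def test_employment_filter_can_flip_direction(self):
        rng = np.random.default_rng(13)
        base = rng.random(168)
        vectors, groups, pids, employment = [], [], [], {}
        # employed controls: identical rhythms; unemployed controls: diverse
        for i in range(5):
            vectors.append(base)
            groups.append("control")
            pids.append(f"ce{i}")
            employment[f"ce{i}"] = "full_time"
        for i in range(8):
            vectors.append(rng.random(168))
            groups.append("control")
            pids.append(f"cu{i}")
            employment[f"cu{i}"] = "other"
        # patients: moderately similar throughout
        shared = rng.random(168)
        for i in range(8):
            vectors.append(shared + rng.random(168) * 0.6)
            groups.append("patient")
            pids.append(f"pa{i}")
            employment[f"pa{i}"] = "full_time" if i < 5 else "other"
        frame = self._frame(vectors, groups, pids)
        emp = pd.Series(employment)
        full = rh.homogeneity_report({"screen": frame})
        employed = rh.homogeneity_report({"screen": frame}, employment=emp, employed_only=True)
        assert full.loc[0, "more_homogeneous"] == "patient"
        assert employed.loc[0, "more_homogeneous"] == "control"


def test_region_summary_partitions_weight():
    w = np.full(168, 1 / 168)
    regions = rh.region_summary(w)
    assert sum(regions.values()) == pytest.approx(1.0)
    assert regions["morning"] == pytest.approx(0.25)
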