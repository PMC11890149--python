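"""Generator contracts: counts, containment, determinism, planted limits."""

import numpy as np
import pandas as pd
import pytest

from momopheno import data_model as dm
from momopheno import synthetic_data as sd


def _config(**kw):
    defaults = dict(
        n_per_group={"control": 2, "mdd": 2},
        group_labels=("control", "mdd"),
        study_days=28,
        seed=11,
        active_phase_days=2,
    )
    defaults.update(kw)
    return sd.CohortConfig(**defaults)


class TestCohort:
    def test_count_conservation(self):
        cfg = sd.CohortConfig(n_per_group=5, study_days=28, seed=0)
        cohort = sd.generate_cohort(cfg)
        assert len(cohort) == 20  # 5 per group x 4 groups

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValueError, match="group"):
            sd.CohortConfig(n_per_group=2, group_labels=("control", "schizo"))

    def test_no_dropout_means_full_followup(self):
        cfg = _config()
        eff = sd.PlantedEffects(dropout_hazard={g: 0.0 for g in sd.GROUPS})
        for rec in sd.generate_cohort(cfg, eff):
            assert rec.exit_date == rec.enroll_date + pd.Timedelta(days=cfg.study_days)

    def test_dropout_hazard_is_binomial_rate(self):
        cfg = sd.CohortConfig(n_per_group={"mdd": 1000}, group_labels=("mdd",),
                              study_days=28, seed=5)
        eff = sd.PlantedEffects(dropout_hazard={g: 0.5 for g in sd.GROUPS})
        cohort = sd.generate_cohort(cfg, eff)
        frac_left_after_1 = np.mean(
            [rec.exit_date == rec.enroll_date + pd.Timedelta(days=14) for rec in cohort]
        )
        assert abs(frac_left_after_1 - 0.5) < 0.05

    def test_exit_never_before_enroll(self):
        for rec in sd.generate_cohort(_config()):
            assert rec.exit_date >= rec.enroll_date


class TestEventStreams:
    def test_degenerate_template_confines_events(self):
        # intensity mass only in Monday 09:00-10:00 -> every call lands there
        template = np.zeros(168)
        template[9] = 1.0
        cfg = _config(n_per_group={"mdd": 2}, group_labels=("mdd",))
        eff = sd.PlantedEffects(rhythm_templates={"mdd": template}, rhythm_noise_sd=0.0)
        calls = sd.generate_event_streams(
            sd.generate_cohort(cfg, eff), eff, cfg, sensors=["call"]
        )["call"]
        local = dm.localize(calls, cfg.timezone)
        assert len(local) > 0
        assert (local["hour_of_week"] == 9).all()

    def test_poisson_total_count_within_3_sigma(self):
        # constant intensity 2 events/h over one participant's enrollment
        cfg = sd.CohortConfig(
            n_per_group={"control": 1}, group_labels=("control",), study_days=210,
            seed=2, enroll_span_days=0,
            daily_rates={"call": 48.0, "sms": 2.5, "screen": 45.0, "app": 30.0},
        )
        eff = sd.PlantedEffects(
            rhythm_templates={"control": np.ones(168)},
            rhythm_noise_sd=0.0,
            activity_factor_sd=0.0,
            dropout_hazard={g: 0.0 for g in sd.GROUPS},
        )
        cohort = sd.generate_cohort(cfg, eff)
        calls = sd.generate_event_streams(cohort, eff, cfg, sensors=["call"])["call"]
        hours = (cohort[0].exit_date - cohort[0].enroll_date).total_seconds() / 3600
        expected = 2.0 * hours
        assert abs(len(calls) - expected) < 3 * np.sqrt(expected)

    def test_event_enums_valid_and_sorted(self, tiny_cohort):
        cfg, eff, cohort = tiny_cohort
        streams = sd.generate_event_streams(cohort, eff, cfg, sensors=["call", "sms", "screen"])
        for sensor, df in streams.items():
            dm.validate_events(df, sensor)  # raises on bad enum/ordering input

    def test_temporal_containment(self, tiny_cohort):
        cfg, eff, cohort = tiny_cohort
        streams = sd.generate_event_streams(
            cohort, eff, cfg, sensors=["call", "battery", "location"]
        )
        bounds = {r.participant_id: (r.enroll_date, r.exit_date) for r in cohort}
        for df in streams.values():
            local = dm.localize(df, cfg.timezone)
            for pid, g in local.groupby("participant_id"):
                enroll, exit_ = bounds[pid]
                assert (g["local_date"] >= enroll).all()
                assert (g["local_date"] < exit_).all()

    def test_determinism_byte_identical(self, tmp_path, tiny_cohort):
        cfg, eff, cohort = tiny_cohort
        for d in ("a", "b"):
            streams = sd.generate_event_streams(cohort, eff, cfg, sensors=["call", "battery"])
            sd.write_streams(streams, tmp_path / d, formats=("csv",))
        for sensor in ("call", "battery"):
            assert (tmp_path / "a" / f"{sensor}.csv").read_bytes() == (
                tmp_path / "b" / f"{sensor}.csv"
            ).read_bytes()

    def test_noiseless_schedule_gives_exact_sleep_epochs(self):
        cfg = _config(
            n_per_group={"control": 1}, group_labels=("control",),
            actigraph_noise=0.0, sleep_jitter_min=0.0, active_phase_days=3,
        )
        eff = sd.PlantedEffects()
        cohort = sd.generate_cohort(cfg, eff)
        acti = sd.generate_event_streams(cohort, eff, cfg, sensors=["actigraph"])["actigraph"]
        local = dm.localize(acti, cfg.timezone)
        sleep = local[local["status"] == "sleep"]
        hours = sleep["timestamp_local"].dt.hour
        assert ((hours >= 23) | (hours < 7)).all()
        # first scheduled night starts exactly at 23:00
        first_night = sleep["timestamp_local"].min()
        assert (first_night.hour, first_night.minute) == (23, 0)


class TestPhq9:
    def test_deterministic_mean_when_all_variance_zero(self, tiny_cohort):
        cfg, _, cohort = tiny_cohort
        eff = sd.PlantedEffects(
            beta={}, random_intercept_sd=0.0, residual_sd=1e-9,
            baseline_phq9={g: 10.0 for g in sd.GROUPS},
        )
        phq = sd.generate_phq9(cohort, eff, config=cfg, response_missing_prob=0.0)
        assert (phq["score"] == 10).all()

    def test_scores_clipped_to_scale(self, tiny_cohort):
        cfg, _, cohort = tiny_cohort
        eff = sd.PlantedEffects(
            beta={}, random_intercept_sd=0.0, residual_sd=1e-9,
            baseline_phq9={g: 30.0 for g in sd.GROUPS},
        )
        phq = sd.generate_phq9(cohort, eff, config=cfg, response_missing_prob=0.0)
        assert (phq["score"] == 27).all()

    def test_scores_integer_in_range(self, tiny_cohort):
        cfg, eff, cohort = tiny_cohort
        phq = sd.generate_phq9(cohort, eff, config=cfg)
        assert phq["score"].between(0, 27).all()
        assert phq["period_index"].ge(0).all()

    def test_window_without_features_flagged(self, tiny_cohort):
        cfg, eff, cohort = tiny_cohort
        # features provided for no dates at all -> every post-baseline window flagged
        daily = pd.DataFrame(
            {"participant_id": ["nobody"], "local_date": [pd.Timestamp("2019-01-01")],
             **{k: [1.0] for k in eff.beta}}
        )
        phq = sd.generate_phq9(cohort, eff, daily_features=daily, config=cfg,
                               response_missing_prob=0.0)
        assert phq.loc[phq["period_index"] > 0, "features_missing"].all()


def test_planted_effect_recovered_end_to_end(tiny_cohort):
    """Slope on a planted predictor is recovered from generated PHQ-9."""
    from momopheno import association as assoc

    rng = np.random.default_rng(42)
    cfg = sd.CohortConfig(
        n_per_group={"mdd": 40}, group_labels=("mdd",), study_days=180, seed=3,
    )
    eff = sd.PlantedEffects(
        beta={"incoming_call_duration": -0.08},
        dropout_hazard={g: 0.0 for g in sd.GROUPS},
        random_intercept_sd=2.0, residual_sd=2.0,
    )
    cohort = sd.generate_cohort(cfg, eff)
    dates = pd.date_range("2019-01-01", periods=300, freq="D")
    daily = pd.concat(
        [
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "local_date": dates,
                    "incoming_call_duration": rng.normal(8, 6, len(dates)),
                }
            )
            for rec in cohort
        ]
    )
    phq = sd.generate_phq9(cohort, eff, daily_features=daily, config=cfg,
                           response_missing_prob=0.0)
    phq = phq[phq["period_index"] > 0]
    windows = assoc.center_within_person(
        assoc.build_windows(daily, phq), ["incoming_call_duration"]
    )
    res = assoc.fit_lmm(windows, ["incoming_call_duration_W"])
    est = res.params["incoming_call_duration_W"]
    se = (res.conf_int.loc["incoming_call_duration_W", "upper"] - est) / 1.96
    assert abs(est - (-0.08)) < 2.5 * se
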