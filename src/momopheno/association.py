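"""Association between 14-day behavioral features and depression severity.

For every PHQ-9 response on local date d, predictors are the means of daily
sensor features over the 14 preceding local dates [d-14, d-1] (the response
day itself is excluded).  Continuous duration-type predictors are
within-person centered (suffix ``_W``): each participant's own mean across
their windows is subtracted, so the fixed effect reflects within-individual
variation.  The model is a random-intercept linear mixed model,

    PHQ9_it = beta_0 + sum_k beta_k x_kit + b_i + e_it,
    b_i ~ N(0, tau^2),  e_it ~ N(0, sigma^2),

fitted by REML (statsmodels MixedLM) with Wald 95% CIs.  Duration
predictors are in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Predictor sets of the four standard sensor-domain models.  ``_W`` marks
#: within-person centered predictors (durations); counts enter raw.
MODEL_SPECS: dict[str, list[str]] = {
    "communication": [
        "incoming_call_duration_W",
        "outgoing_call_duration_W",
        "n_incoming_sms",
        "n_outgoing_sms",
    ],
    "location": [
        "log_location_variance_W",
        "normalized_entropy_W",
        "distance_km_W",
        "n_significant_places",
        "pct_time_home",
    ],
    "apps": [
        "social_media_W",
        "communication_app_W",
        "games_W",
        "leisure_W",
        "screen_use_W",
    ],
    "accel": [
        "magnitude_sd_morning",
        "magnitude_sd_afternoon",
        "magnitude_sd_evening",
        "magnitude_sd_night",
    ],
}

LOW_COVERAGE_MIN_DAYS = 4


def build_windows(
    daily_features: pd.DataFrame,
    phq9: pd.DataFrame,
    window_days: int = 14,
) -> pd.DataFrame:
    """Mean daily features over the 14 local dates preceding each PHQ-9.

    ``daily_features``: one row per participant x local_date, wide feature
    columns.  Adds ``<feature>_days`` coverage counts; features with zero
    contributing days are missing, and windows with any feature below
    4 days are flagged ``low_coverage``.
    """
    feat_cols = [c for c in daily_features.columns if c not in ("participant_id", "local_date")]
    daily = daily_features.copy()
    daily["local_date"] = pd.to_datetime(daily["local_date"])
    by_pid = {pid: g.set_index("local_date") for pid, g in daily.groupby("participant_id")}
    rows = []
    for _, resp in phq9.iterrows():
        pid = resp["participant_id"]
        d = pd.to_datetime(resp["response_date"])
        row = {
            "participant_id": pid,
            "response_date": d,
            "period_index": resp.get("period_index", np.nan),
            "phq9": resp["score"],
        }
        g = by_pid.get(pid)
        coverages = []
        if g is not None:
            win = g[(g.index >= d - pd.Timedelta(days=window_days)) & (g.index < d)]
            for c in feat_cols:
                vals = win[c].dropna() if c in win.columns else pd.Series(dtype=float)
                row[c] = vals.mean() if len(vals) else np.nan
                row[f"{c}_days"] = len(vals)
                coverages.append(len(vals))
        else:
            for c in feat_cols:
                row[c] = np.nan
                row[f"{c}_days"] = 0
                coverages.append(0)
        row["low_coverage"] = any(n < LOW_COVERAGE_MIN_DAYS for n in coverages)
        rows.append(row)
    return pd.DataFrame(rows)


def center_within_person(
    windows: pd.DataFrame, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Add ``_W`` columns: raw minus the participant's mean over their windows.

    Centering is idempotent in the sense that centering the centered column
    again changes nothing (its per-person mean is already 0).
    """
    out = windows.copy()
    if features is None:
        features = [
            c
            for c in out.columns
            if c not in ("participant_id", "response_date", "period_index", "phq9", "low_coverage")
            and not c.endswith("_days")
            and not c.endswith("_W")
            and pd.api.types.is_numeric_dtype(out[c])
        ]
    for c in features:
        out[f"{c}_W"] = out[c] - out.groupby("participant_id")[c].transform("mean")
    return out


def day_part_accel_features(hourly_sd: pd.DataFrame) -> pd.DataFrame:
    """Daily mean magnitude SD by day part (morning/afternoon/evening/night).

    Day parts: local hours 6-12 (morning), 12-18 (afternoon), 18-24
    (evening), 0-6 (night).  One row per participant x local_date.
    """
    df = hourly_sd.copy()
    part = np.select(
        [df["local_hour"] < 6, df["local_hour"] < 12, df["local_hour"] < 18],
        ["night", "morning", "afternoon"],
        default="evening",
    )
    df["day_part"] = part
    wide = (
        df.groupby(["participant_id", "local_date", "day_part"], observed=True)["magnitude_sd"]
        .mean()
        .unstack("day_part")
    )
    wide = wide.rename(columns=lambda p: f"magnitude_sd_{p}").reset_index()
    wide.columns.name = None
    return wide


@dataclass
class LmmResult:
    """Fitted random-intercept model for one sensor domain."""

    model_name: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    pvalues: pd.Series
    intercept_sd: float
    residual_sd: float
    n_obs: int
    n_participants: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        """Table-shaped summary: estimate (95% CI), P per predictor."""
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "ci_lower": self.conf_int["lower"],
                "ci_upper": self.conf_int["upper"],
                "p_value": self.pvalues,
            }
        )
        out.index.name = "predictor"
        return out


class DepressionSeverityModel:
    """Random-intercept linear mixed model of PHQ-9 on sensor features.

    statsmodels-style: construct from a windows table, then ``fit()``.

    Parameters
    ----------
    windows : table with ``participant_id``, ``phq9`` and predictor columns.
    predictors : fixed-effect columns; defaults to one of ``MODEL_SPECS``
        when ``model_name`` is a known domain.
    """

    def __init__(
        self,
        windows: pd.DataFrame,
        predictors: Sequence[str] | None = None,
        model_name: str = "custom",
        response: str = "phq9",
        min_participants: int = 10,
    ) -> None:
        if predictors is None:
            if model_name not in MODEL_SPECS:
                raise ValueError("predictors required for a custom model")
            predictors = MODEL_SPECS[model_name]
        self.model_name = model_name
        self.predictors = list(predictors)
        self.response = response
        cols = ["participant_id", response, *self.predictors]
        missing = [c for c in cols if c not in windows.columns]
        if missing:
            raise ValueError(f"windows table missing columns {missing}")
        data = windows.loc[:, cols].dropna()  # listwise within this model only
        counts = data.groupby("participant_id").size()
        n_repeat = int((counts >= 2).sum())
        if n_repeat < min_participants:
            raise ValueError(
                f"need >= {min_participants} participants with >= 2 windows, have {n_repeat}"
            )
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_daily(
        cls,
        daily_features: pd.DataFrame,
        phq9: pd.DataFrame,
        model_name: str,
        window_days: int = 14,
        **kwargs,
    ) -> "DepressionSeverityModel":
        """Convenience constructor: windows + centering from daily features."""
        windows = center_within_person(build_windows(daily_features, phq9, window_days))
        return cls(windows, model_name=model_name, **kwargs)

    def fit(self, reml: bool = True) -> LmmResult:
        """REML fit with Wald 95% CIs; retries optimizers on non-convergence."""
        endog = self.data[self.response].to_numpy(dtype=float)
        exog = sm.add_constant(self.data[self.predictors].astype(float), has_constant="add")
        groups = self.data["participant_id"].to_numpy()
        if np.allclose(endog, endog[0]):
            zero = pd.Series(0.0, index=exog.columns)
            ci = pd.DataFrame({"lower": zero, "upper": zero})
            return LmmResult(self.model_name, zero, ci, pd.Series(np.nan, index=exog.columns),
                             0.0, 0.0, len(endog), self.data["participant_id"].nunique(), True)
        model = sm.MixedLM(endog, exog, groups=groups)
        fit = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=200)
            except Exception as exc:  # singular fits raise LinAlgError
                last_exc = exc
                continue
            fit = cand
            if getattr(fit, "converged", True):
                break
        if fit is None:
            raise RuntimeError(f"mixed model failed to fit: {last_exc}")
        params = fit.params.drop(labels=[c for c in fit.params.index if c == "Group Var"])
        ci = fit.conf_int().loc[params.index]
        ci.columns = ["lower", "upper"]
        intercept_var = float(np.squeeze(fit.cov_re)) if fit.cov_re.size else 0.0
        return LmmResult(
            model_name=self.model_name,
            params=params,
            conf_int=ci,
            pvalues=fit.pvalues.loc[params.index],
            intercept_sd=float(np.sqrt(max(intercept_var, 0.0))),
            residual_sd=float(np.sqrt(fit.scale)),
            n_obs=int(fit.nobs),
            n_participants=int(self.data["participant_id"].nunique()),
            converged=bool(getattr(fit, "converged", True)),
        )


def fit_lmm(
    windows: pd.DataFrame,
    predictors: Sequence[str] | None = None,
    model_name: str = "custom",
    **kwargs,
) -> LmmResult:
    """Functional wrapper around :class:`DepressionSeverityModel`."""
    return DepressionSeverityModel(windows, predictors, model_name=model_name, **kwargs).fit()
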