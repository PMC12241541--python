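"""Trial-level mixed models for accuracy and response time.

Accuracy is modelled on the probability scale (identity link) so the
difficulty coefficient reads directly as a per-level change in proportion
correct; a logistic variant is available.  Response time uses correct
trials only.  Both models include the testing day and treat participant
(with scans nested inside) as the repeated-measure grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BehaviorFit", "fit_accuracy_model", "fit_rt_model"]


@dataclass
class BehaviorFit:
    outcome: str
    slope_difficulty: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float
    day_slope: float
    day_p_value: float
    n_obs: int
    converged: bool
    model: str


def _prepare(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    if df["difficulty"].nunique() < 2:
        raise ValueError("need at least 2 difficulty levels")
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    df["difficulty"] = df["difficulty"].astype(float)
    df["day"] = df["day"].astype(float) - 1.0  # 0/1 coding
    df["scan_uid"] = (
        df["day"].astype(int).astype(str) + "_" + df["scan"].astype(int).astype(str)
    )
    return df


def _fit_mixed(df: pd.DataFrame, formula: str, outcome: str) -> BehaviorFit:
    import statsmodels.formula.api as smf

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula,
                df,
                groups=df["participant_id"],
                vc_formula={"scan": "0 + C(scan_uid)"},
            )
            fit = model.fit(reml=True, method="lbfgs")
            if not fit.converged:
                raise RuntimeError("mixed model did not converge")
        except Exception:
            # simplify to participant-only random intercept, then OLS
            try:
                model = smf.mixedlm(formula, df, groups=df["participant_id"])
                fit = model.fit(reml=True, method="lbfgs")
                converged = bool(fit.converged)
            except Exception:
                fit = smf.ols(formula, df).fit()
                converged = False
    ci = fit.conf_int().loc["difficulty"]
    df_resid = int(fit.nobs - len(fit.fe_params) if hasattr(fit, "fe_params") else fit.df_resid)
    return BehaviorFit(
        outcome=outcome,
        slope_difficulty=float(fit.params["difficulty"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t_stat=float(fit.tvalues["difficulty"]),
        df=df_resid,
        p_value=float(fit.pvalues["difficulty"]),
        day_slope=float(fit.params["day"]),
        day_p_value=float(fit.pvalues["day"]),
        n_obs=int(fit.nobs),
        converged=converged,
        model="linear-mixed",
    )


def fit_accuracy_model(trials: pd.DataFrame, link: str = "identity") -> BehaviorFit:
    """Trial-level accuracy on difficulty and day.

    With the default identity link the slope is a per-level change in
    proportion correct (e.g. −0.09 = nine percentage points per level).
    ``link="logit"`` fits a cluster-robust logistic model instead.
    """
    df = _prepare(trials)
    correct = df["correct"]
    if not set(pd.unique(correct)) <= {0, 1, True, False}:
        raise ValueError("accuracy outcome must be binary")
    df["correct"] = correct.astype(float)
    if link == "identity":
        return _fit_mixed(df, "correct ~ difficulty + day", "accuracy")
    if link == "logit":
        import statsmodels.formula.api as smf

        fit = smf.logit("correct ~ difficulty + day", df).fit(
            disp=False, cov_type="cluster", cov_kwds={"groups": df["participant_id"]}
        )
        ci = fit.conf_int().loc["difficulty"]
        return BehaviorFit(
            outcome="accuracy",
            slope_difficulty=float(fit.params["difficulty"]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            t_stat=float(fit.tvalues["difficulty"]),
            df=int(fit.df_resid),
            p_value=float(fit.pvalues["difficulty"]),
            day_slope=float(fit.params["day"]),
            day_p_value=float(fit.pvalues["day"]),
            n_obs=int(fit.nobs),
            converged=bool(fit.mle_retvals.get("converged", True)),
            model="logistic-cluster",
        )
    raise ValueError(f"unknown link {link!r}")


def fit_rt_model(trials: pd.DataFrame, correct_only: bool = True) -> BehaviorFit:
    """Response time (s) on difficulty and day, correct trials only by default."""
    df = _prepare(trials)
    if correct_only:
        df = df[df["correct"].astype(bool)]
        missing = sorted(
            set(trials["difficulty"].unique()) - set(df["difficulty"].astype(int).unique())
        )
        if missing:
            raise ValueError(f"no correct trials at difficulty level(s) {missing}")
    fit = _fit_mixed(df, "response_time ~ difficulty + day", "rt")
    fit.n_obs = len(df)
    return fit
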