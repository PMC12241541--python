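"""Quadrant assignment, net-BOLD statistic and difficulty effects with FDR.

Regions are placed in a two-axis plane (difficulty loading, performance
loading) and split into four quadrants; the net BOLD response of a region
is the signed area between its FIR time course and zero; a per-region
mixed model relates net BOLD to difficulty, with Benjamini–Hochberg control
across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_quadrants",
    "net_bold",
    "net_bold_table",
    "benjamini_hochberg",
    "difficulty_effect",
]

QUADRANT_LABELS = {
    1: "hard-correct",
    2: "easy-correct",
    3: "easy-incorrect",
    4: "hard-incorrect",
}


def assign_quadrants(
    loadings: np.ndarray, region_labels: list[str] | None = None
) -> pd.DataFrame:
    """Assign each region to a quadrant of the (difficulty, performance) plane.

    Q1: difficulty > 0, performance > 0 (hard & correct); Q2: difficulty < 0,
    performance > 0; Q3: both < 0; Q4: difficulty > 0, performance < 0.
    Zero loadings count as positive (deterministic tie rule).
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[1] != 2:
        raise ValueError("loadings must be regions x 2")
    if not np.isfinite(loadings).all():
        raise ValueError("non-finite loadings")
    diff, perf = loadings[:, 0] >= 0, loadings[:, 1] >= 0
    quadrant = np.where(
        diff & perf, 1, np.where(~diff & perf, 2, np.where(~diff & ~perf, 3, 4))
    )
    if region_labels is None:
        region_labels = [f"region_{i + 1:03d}" for i in range(len(loadings))]
    return pd.DataFrame(
        {
            "region_label": region_labels,
            "loading_difficulty": loadings[:, 0],
            "loading_performance": loadings[:, 1],
            "quadrant": quadrant,
        }
    )


def net_bold(beta_series: np.ndarray, tr: float = 1.0) -> float:
    """Signed area between a beta time course and y = 0 (rectangle rule)."""
    beta_series = np.asarray(beta_series, dtype=float)
    if np.isnan(beta_series).any():
        raise ValueError("NaN in beta series")
    return float(beta_series.sum() * tr)


def net_bold_table(
    all_betas, conditions, region_indices: np.ndarray, tr: float = 1.0
) -> pd.DataFrame:
    """Tidy net-BOLD values: one row per (participant, condition, region)."""
    difficulty_of = {"easy-correct": 0, "medium-correct": 1, "hard-correct": 2}
    rows = []
    for fb in all_betas:
        for cond in conditions:
            if cond not in fb.betas:
                continue
            block = fb.betas[cond]
            for r in region_indices:
                label = fb.region_labels[r] if fb.region_labels else f"region_{r + 1:03d}"
                rows.append(
                    (
                        fb.participant_id,
                        cond,
                        difficulty_of.get(cond, np.nan),
                        int(r),
                        label,
                        net_bold(block[r], tr),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "difficulty", "region", "region_label", "net_bold"],
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class RegionFit:
    slope: float
    t_stat: float
    p_value: float


def _fit_region_mixed(sub: pd.DataFrame) -> RegionFit:
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("net_bold ~ difficulty", sub, groups=sub["participant_id"])
        fit = model.fit(reml=True, method="lbfgs")
    return RegionFit(
        slope=float(fit.fe_params["difficulty"]),
        t_stat=float(fit.tvalues["difficulty"]),
        p_value=float(fit.pvalues["difficulty"]),
    )


def _fit_region_ols(sub: pd.DataFrame) -> RegionFit:
    """Within-participant OLS: difficulty slope with participant fixed effects.

    Closed form via the Frisch–Waugh theorem: demean outcome and difficulty
    within participant, regress, and test with df = n − n_participants − 1.
    Equivalent to ``net_bold ~ difficulty + C(participant_id)``.
    """
    from scipy.stats import t as t_dist

    y = sub["net_bold"].to_numpy(dtype=float)
    d = sub["difficulty"].to_numpy(dtype=float)
    codes, _ = pd.factorize(sub["participant_id"])
    n_groups = codes.max() + 1
    y = y - np.bincount(codes, weights=y)[codes] / np.bincount(codes)[codes]
    d = d - np.bincount(codes, weights=d)[codes] / np.bincount(codes)[codes]
    sxx = d @ d
    if sxx == 0:
        raise np.linalg.LinAlgError("no within-participant difficulty variation")
    slope = (d @ y) / sxx
    resid = y - slope * d
    df = len(y) - n_groups - 1
    if df <= 0:
        raise np.linalg.LinAlgError("not enough observations for fixed-effect fit")
    se = np.sqrt(resid @ resid / df / sxx)
    t_stat = slope / se
    p = 2 * t_dist.sf(abs(t_stat), df)
    return RegionFit(slope=float(slope), t_stat=float(t_stat), p_value=float(p))


def difficulty_effect(
    table: pd.DataFrame, alpha: float = 0.05, method: str = "mixed"
) -> pd.DataFrame:
    """Per-region slope of net BOLD on difficulty with BH FDR across regions.

    ``table`` comes from :func:`net_bold_table` restricted to the difficulty
    conditions.  ``method`` "mixed" fits a participant-random-intercept
    model per region; "ols" uses participant fixed effects (identical slope
    on balanced data, much faster).  Singular fits are flagged and excluded
    from the FDR correction.
    """
    if table["difficulty"].nunique() < 2:
        raise ValueError("need at least 2 difficulty levels")
    if table["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if method not in ("mixed", "ols"):
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for (region, label), sub in table.groupby(["region", "region_label"], sort=True):
        used = method
        res, ok = None, False
        if method == "mixed":
            try:
                res = _fit_region_mixed(sub)
                ok = np.isfinite(res.p_value) and np.isfinite(res.slope)
            except Exception:
                ok = False
        if not ok:
            # singular random-intercept fit: fall back to participant fixed effects
            used = "ols"
            try:
                res = _fit_region_ols(sub)
                ok = np.isfinite(res.p_value) and np.isfinite(res.slope)
            except Exception:
                res, ok = RegionFit(np.nan, np.nan, np.nan), False
        if not ok:
            warnings.warn(f"region {label}: singular fit, excluded from FDR")
        rows.append((int(region), label, res.slope, res.t_stat, res.p_value, used, ok))
    out = pd.DataFrame(
        rows,
        columns=["region", "region_label", "slope", "t_stat", "p_value", "fit_method", "valid"],
    )
    out["q_value"] = np.nan
    valid = out["valid"].to_numpy()
    if valid.any():
        out.loc[valid, "q_value"] = benjamini_hochberg(out.loc[valid, "p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out
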