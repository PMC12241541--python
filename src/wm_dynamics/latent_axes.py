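"""Discriminant axes of trial-locked BOLD in a PCA-reduced space.

The observation matrix stacks one row per (participant, condition,
timepoint) over region columns.  After per-slice z-scoring and PCA, linear
discriminant classifiers are swept across timepoints and PC counts under
subject-grouped cross-validation; the two resulting discriminant directions
are orthonormalised by Gram–Schmidt and used to project regions and
condition trajectories into a two-axis plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BetaStack",
    "LatentSpace",
    "SweepGrid",
    "LdaAxes",
    "stack_betas",
    "zscore_timepoints",
    "fit_pca",
    "balanced_accuracy",
    "subject_folds",
    "lda_sweep",
    "select_operating_point",
    "train_final_lda",
    "fisher_lda",
    "orthogonalize_axes",
    "region_loadings",
    "condition_trajectories",
]


@dataclass
class BetaStack:
    """Beta estimates as a dense array: participants x conditions x timepoints x regions."""

    data: np.ndarray
    participants: list[str]
    conditions: list[str]
    region_labels: list[str] | None = None

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


def stack_betas(all_betas: Sequence, conditions: Sequence[str]) -> BetaStack:
    """Collect per-participant ``FirBetas`` into a dense stack.

    Participants missing any requested condition are dropped (e.g. no
    incorrect Hard trials), with the retained id list recorded.
    """
    kept, rows = [], []
    for fb in all_betas:
        if not all(c in fb.betas for c in conditions):
            continue
        rows.append(np.stack([fb.betas[c].T for c in conditions]))  # cond x time x regions
        kept.append(fb.participant_id)
    if not rows:
        raise ValueError("no participant has all requested conditions")
    first = next(iter(all_betas))
    return BetaStack(
        data=np.stack(rows),
        participants=kept,
        conditions=list(conditions),
        region_labels=first.region_labels,
    )


def zscore_timepoints(stack: BetaStack) -> BetaStack:
    """Z-score each (participant, condition, timepoint) vector across regions.

    Uses the population standard deviation so every slice has mean 0 and
    s.d. exactly 1.  A zero-spread slice is an error (degenerate data).
    """
    data = stack.data
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    bad = np.argwhere(sd[..., 0] == 0)
    if bad.size:
        p, c, t = bad[0]
        raise ValueError(
            f"zero spread across regions for participant {stack.participants[p]}, "
            f"condition {stack.conditions[c]}, timepoint {t}"
        )
    return BetaStack(
        data=(data - mean) / sd,
        participants=stack.participants,
        conditions=stack.conditions,
        region_labels=stack.region_labels,
    )


@dataclass
class LatentSpace:
    """PCA basis over regions with observation scores.

    ``components`` is n_pcs x regions (orthonormal rows); ``scores`` has
    shape participants x conditions x timepoints x n_pcs and holds the
    centred data projected on the components.
    """

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    participants: list[str]
    conditions: list[str]
    region_labels: list[str] | None = None

    @property
    def n_pcs(self) -> int:
        return self.components.shape[0]


def fit_pca(stack: BetaStack, n_max: int = 40) -> LatentSpace:
    """PCA of the stacked observation matrix (rows = participant x condition x timepoint)."""
    P, C, T, R = stack.data.shape
    X = stack.data.reshape(P * C * T, R)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    rank = int((s > s[0] * 1e-12).sum())
    if n_max > rank:
        import warnings

        warnings.warn(f"n_max={n_max} exceeds data rank {rank}; truncating")
        n_max = rank
    comps = vt[:n_max]
    scores = (Xc @ comps.T).reshape(P, C, T, n_max)
    return LatentSpace(
        components=comps,
        explained_variance_ratio=var[:n_max] / total,
        scores=scores,
        mean=mean,
        participants=stack.participants,
        conditions=stack.conditions,
        region_labels=stack.region_labels,
    )


def balanced_accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean of sensitivity and specificity for binary labels."""
    truth = np.asarray(truth).astype(bool)
    predicted = np.asarray(predicted).astype(bool)
    if truth.all() or (~truth).all():
        raise ValueError("both classes must be present in truth")
    sens = (predicted & truth).sum() / truth.sum()
    spec = (~predicted & ~truth).sum() / (~truth).sum()
    return float((sens + spec) / 2)


def subject_folds(
    subjects: Sequence[str], n_folds: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Partition observation indices into folds that never split a subject."""
    subjects = np.asarray(subjects)
    unique = np.unique(subjects)
    if len(unique) < n_folds:
        raise ValueError(f"need >= {n_folds} distinct subjects, got {len(unique)}")
    order = np.random.default_rng(seed).permutation(unique)
    groups = np.array_split(order, n_folds)
    return [np.flatnonzero(np.isin(subjects, g)) for g in groups]


def fisher_lda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None
) -> np.ndarray:
    """Closed-form Fisher discriminant direction w ∝ Σ_w⁻¹ (μ₁ − μ₀).

    The pooled within-class covariance is optionally shrunk towards a scaled
    identity; when it is singular and no shrinkage is given, a small
    automatic ridge is applied.  The sign convention makes class 1 project
    positive.  Returns a unit-norm direction.
    """
    y = np.asarray(y).astype(bool)
    X0, X1 = X[~y], X[y]
    if len(X0) == 0 or len(X1) == 0:
        raise ValueError("both classes must be present")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1) + np.cov(
        X1, rowvar=False, ddof=1
    ) * (len(X1) - 1)
    S = np.atleast_2d(S) / max(len(X) - 2, 1)
    p = S.shape[0]
    if shrinkage is not None:
        S = (1 - shrinkage) * S + shrinkage * (np.trace(S) / p) * np.eye(p)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError:
        S = S + 1e-8 * max(np.trace(S) / p, 1e-12) * np.eye(p)
        w = np.linalg.solve(S, mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return w
    w = w / norm
    if (mu1 - mu0) @ w < 0:
        w = -w
    return w


@dataclass
class SweepGrid:
    """Cross-validated balanced accuracy over (timepoint, PC count) cells."""

    scores: np.ndarray  # timepoints x pc counts; NaN = invalid cell
    timepoints: np.ndarray  # 1-based timepoint ids
    pc_counts: np.ndarray
    n_folds: int
    seed: int
    meta: dict = field(default_factory=dict)


def _classify_cell(
    scores_t: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    k: int,
    folds: list[np.ndarray],
    shrinkage: float | None,
) -> float:
    X = scores_t[:, :k]
    accs = []
    for test in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test] = False
        ytr = y[mask]
        if ytr.all() or (~ytr).all():
            return np.nan
        w = fisher_lda(X[mask], ytr, shrinkage)
        mu0 = X[mask][~ytr].mean(axis=0) @ w
        mu1 = X[mask][ytr].mean(axis=0) @ w
        thr = (mu0 + mu1) / 2
        pred = X[test] @ w > thr
        accs.append(balanced_accuracy(y[test], pred))
    return float(np.mean(accs))


def lda_sweep(
    latent: LatentSpace,
    condition_pair: tuple[str, str],
    t_range: Sequence[int] | None = None,
    pc_range: Sequence[int] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    shrinkage: float | None = 0.1,
) -> SweepGrid:
    """Sweep LDA balanced accuracy over timepoints and PC counts.

    Observations are per (participant, condition) score vectors at each
    timepoint; folds group by participant so no subject appears on both
    sides of a split.  Class 1 is ``condition_pair[1]``.  Cells whose
    training split loses a class are NaN (flagged, not zero).
    """
    c0, c1 = (latent.conditions.index(c) for c in condition_pair)
    P, _, T, K = latent.scores.shape
    t_ids = np.asarray(t_range if t_range is not None else np.arange(1, T + 1))
    k_ids = np.asarray(pc_range if pc_range is not None else np.arange(1, min(40, K) + 1))
    if k_ids.max() > K:
        raise ValueError(f"pc_range exceeds available PCs ({K})")

    # observation layout: participants x {c0, c1}
    subjects = np.repeat(latent.participants, 2)
    y = np.tile([False, True], P)
    folds = subject_folds(subjects, n_folds=n_folds, seed=seed)

    grid = np.full((len(t_ids), len(k_ids)), np.nan)
    for i, t in enumerate(t_ids):
        obs = np.empty((2 * P, K))
        obs[0::2] = latent.scores[:, c0, t - 1, :]
        obs[1::2] = latent.scores[:, c1, t - 1, :]
        for j, k in enumerate(k_ids):
            grid[i, j] = _classify_cell(obs, y, subjects, int(k), folds, shrinkage)
    return SweepGrid(
        scores=grid,
        timepoints=t_ids,
        pc_counts=k_ids,
        n_folds=n_folds,
        seed=seed,
        meta={"condition_pair": condition_pair, "folds": folds},
    )


def select_operating_point(grid: SweepGrid) -> tuple[int, int]:
    """Best (timepoint, PC count): grid maximum, ties resolved to the
    earliest timepoint, then to the fewest PCs reaching that maximum there."""
    scores = grid.scores
    if np.isnan(scores).all():
        raise ValueError("all sweep cells are invalid")
    best = np.nanmax(scores)
    t_idx, k_idx = np.nonzero(scores == best)
    first_t = t_idx.min()
    first_k = k_idx[t_idx == first_t].min()
    return int(grid.timepoints[first_t]), int(grid.pc_counts[first_k])


def train_final_lda(
    latent: LatentSpace,
    condition_pair: tuple[str, str],
    timepoint: int,
    n_pcs: int = 13,
    shrinkage: float | None = 0.1,
) -> np.ndarray:
    """Train the final discriminant on all participants at one timepoint.

    Returns a PC-space direction, zero-padded to the full latent
    dimensionality, unit norm, with ``condition_pair[1]`` projecting
    positive.
    """
    if n_pcs > latent.n_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds available PCs ({latent.n_pcs})")
    c0, c1 = (latent.conditions.index(c) for c in condition_pair)
    X = np.vstack(
        [latent.scores[:, c0, timepoint - 1, :n_pcs], latent.scores[:, c1, timepoint - 1, :n_pcs]]
    )
    y = np.r_[np.zeros(len(latent.participants)), np.ones(len(latent.participants))]
    w = fisher_lda(X, y.astype(bool), shrinkage)
    full = np.zeros(latent.n_pcs)
    full[:n_pcs] = w
    return full


@dataclass
class LdaAxes:
    """Raw and Gram–Schmidt-orthonormalised discriminant directions in PC space."""

    axis1_raw: np.ndarray
    axis2_raw: np.ndarray
    axis1_orth: np.ndarray
    axis2_orth: np.ndarray
    corr_with_raw: tuple[float, float]
    operating_points: dict = field(default_factory=dict)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(abs(a @ b) / denom) if denom > 0 else np.nan


def orthogonalize_axes(axis1: np.ndarray, axis2: np.ndarray) -> LdaAxes:
    """Normalise axis 1 and remove its component from axis 2 (Gram–Schmidt).

    ``corr_with_raw`` records |Pearson r| between each orthonormalised axis
    and its raw counterpart.  Collinear inputs are an error — the second
    axis would be undefined.
    """
    n1, n2 = np.linalg.norm(axis1), np.linalg.norm(axis2)
    if n1 == 0 or n2 == 0:
        raise ValueError("axes must be non-zero")
    u1 = axis1 / n1
    resid = axis2 - (axis2 @ u1) * u1
    rnorm = np.linalg.norm(resid)
    if rnorm < 1e-10 * n2:
        raise ValueError("axes are collinear; orthogonalised second axis undefined")
    u2 = resid / rnorm
    return LdaAxes(
        axis1_raw=axis1,
        axis2_raw=axis2,
        axis1_orth=u1,
        axis2_orth=u2,
        corr_with_raw=(_abs_corr(u1, axis1), _abs_corr(u2, axis2)),
    )


def region_loadings(latent: LatentSpace, axes: LdaAxes) -> np.ndarray:
    """Map each region onto the two orthonormal axes: regions x 2."""
    if axes.axis1_orth.shape[0] != latent.n_pcs:
        raise ValueError("axes do not live in this latent basis")
    A = np.column_stack([axes.axis1_orth, axes.axis2_orth])
    return latent.components.T @ A


def condition_trajectories(latent: LatentSpace, axes: LdaAxes) -> np.ndarray:
    """Participant-mean condition trajectories: conditions x timepoints x 2."""
    if axes.axis1_orth.shape[0] != latent.n_pcs:
        raise ValueError("axes do not live in this latent basis")
    A = np.column_stack([axes.axis1_orth, axes.axis2_orth])
    mean_scores = latent.scores.mean(axis=0)  # conditions x timepoints x n_pcs
    return mean_scores @ A
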