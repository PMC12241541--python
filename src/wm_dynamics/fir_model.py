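"""Finite impulse response (FIR) modelling of trial-locked BOLD activity.

Provides the canonical double-gamma haemodynamic response function (HRF),
a data-driven choice of FIR window length, construction of indicator-based
FIR design matrices with day/scan nuisance columns, and per-participant
least-squares fitting that returns time-resolved beta estimates per
condition and region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HrfSpec",
    "FirDesign",
    "FirBetas",
    "canonical_hrf",
    "trial_response_shape",
    "response_window",
    "label_conditions",
    "build_fir_design",
    "fit_fir",
    "fit_participant_betas",
    "CONDITIONS_DIFFICULTY",
    "CONDITION_HARD_INCORRECT",
]

#: condition labels for the difficulty model (correct trials only)
CONDITIONS_DIFFICULTY = ("easy-correct", "medium-correct", "hard-correct")
#: condition label for the error model
CONDITION_HARD_INCORRECT = "hard-incorrect"

_DIFFICULTY_NAMES = {0: "easy", 1: "medium", 2: "hard"}


@dataclass(frozen=True)
class HrfSpec:
    """Parameters of the canonical double-gamma HRF (SPM-style defaults)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    tr: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "peak_undershoot_ratio",
            "tr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfSpec.{name} must be positive")


def canonical_hrf(
    spec: HrfSpec = HrfSpec(), length: float = 32.0, dt: float | None = None
) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``[0, length)`` at ``dt``.

    The kernel is the difference of two gamma densities (peak minus scaled
    undershoot), peak-normalised; its value at t = 0 is exactly 0.
    """
    if length < (dt or spec.tr):
        raise ValueError("length must cover at least one sample")
    dt = spec.tr if dt is None else dt
    t = np.arange(0.0, length, dt)
    peak = gamma_dist.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    kernel = peak - under / spec.peak_undershoot_ratio
    return kernel / kernel.max()


def trial_response_shape(
    trial_duration: float, spec: HrfSpec = HrfSpec(), n_frames: int | None = None
) -> np.ndarray:
    """Expected BOLD response to one trial: boxcar convolved with the HRF.

    Sampled at TR, peak-normalised, optionally truncated to ``n_frames``.
    """
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    n_box = max(int(round(trial_duration / spec.tr)), 1)
    hrf = canonical_hrf(spec, length=32.0 + trial_duration)
    conv = np.convolve(np.ones(n_box), hrf)
    conv = conv / conv.max()
    if n_frames is not None:
        conv = conv[:n_frames]
    return conv


def response_window(trial_duration: float, spec: HrfSpec = HrfSpec()) -> int:
    """FIR window length in frames for a trial of ``trial_duration`` seconds.

    Convolves a boxcar with the canonical HRF at TR resolution and returns
    ``index of first strictly negative sample + 1`` — the number of frames
    during which the expected response is non-negative.
    """
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    n_box = max(int(round(trial_duration / spec.tr)), 1)
    horizon = 64.0 + trial_duration
    hrf = canonical_hrf(spec, length=horizon)
    conv = np.convolve(np.ones(n_box), hrf)
    negative = np.flatnonzero(conv < 0)
    if negative.size == 0:
        raise ValueError("convolved response never goes negative; degenerate HRF spec")
    return int(negative[0]) + 1


def label_conditions(trials: pd.DataFrame) -> pd.Series:
    """Assign each trial a condition label, or ``None`` if unmodelled.

    Correct trials map to ``<difficulty>-correct``; incorrect Hard trials to
    ``hard-incorrect``; incorrect Easy/Medium trials are left unmodelled.
    """
    labels = []
    for _, row in trials.iterrows():
        name = _DIFFICULTY_NAMES[int(row["difficulty"])]
        if bool(row["correct"]):
            labels.append(f"{name}-correct")
        elif name == "hard":
            labels.append(CONDITION_HARD_INCORRECT)
        else:
            labels.append(None)
    return pd.Series(labels, index=trials.index, dtype=object)


@dataclass
class FirDesign:
    """FIR design matrix over the concatenated frame axis of all runs."""

    matrix: np.ndarray
    labels: list[str]
    conditions: tuple[str, ...]
    window: int
    n_frames_per_run: int
    n_runs: int
    fir_slice: slice = field(init=False)

    def __post_init__(self) -> None:
        self.fir_slice = slice(0, len(self.conditions) * self.window)

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def _onset_frame(onset: float, tr: float, strict: bool, atol: float = 1e-6) -> int:
    frame = int(round(onset / tr))
    if strict and abs(onset - frame * tr) > atol:
        raise ValueError(f"trial onset {onset} is off the {tr} s frame grid")
    return frame


def build_fir_design(
    trials: pd.DataFrame,
    conditions: Sequence[str],
    window: int,
    n_frames_per_run: int,
    tr: float = 1.0,
    strict_grid: bool = False,
) -> FirDesign:
    """Build the indicator FIR design plus day/scan nuisance columns.

    ``trials`` must carry ``day``, ``scan``, ``onset`` and ``condition``
    columns for a single participant.  One 0/1 column is emitted per
    (condition, timepoint offset); runs are laid out consecutively on the
    concatenated time axis in (day, scan) order.  Nuisance columns are a
    single day indicator (day 2) plus one indicator per scan.

    Off-grid onsets are rounded to the nearest frame; with ``strict_grid``
    they raise instead (tolerance 1e-6 s).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    conditions = tuple(conditions)

    runs = sorted(set(zip(trials["day"].astype(int), trials["scan"].astype(int))))
    run_offset = {run: i * n_frames_per_run for i, run in enumerate(runs)}
    n_frames = len(runs) * n_frames_per_run

    n_fir = len(conditions) * window
    fir = np.zeros((n_frames, n_fir))
    cond_counts = {c: 0 for c in conditions}
    for _, row in trials.iterrows():
        cond = row.get("condition")
        if cond not in cond_counts:
            continue
        cond_counts[cond] += 1
        base = run_offset[(int(row["day"]), int(row["scan"]))]
        frame = base + _onset_frame(float(row["onset"]), tr, strict_grid)
        c = conditions.index(cond)
        for tau in range(window):
            if frame + tau < base + n_frames_per_run:
                fir[frame + tau, c * window + tau] = 1.0
    for cond, count in cond_counts.items():
        if count == 0:
            warnings.warn(f"condition {cond!r} has no trials; its FIR columns are all zero")

    day = np.zeros((n_frames, 1))
    scans = np.zeros((n_frames, len(runs)))
    for i, run in enumerate(runs):
        lo = run_offset[run]
        hi = lo + n_frames_per_run
        scans[lo:hi, i] = 1.0
        if run[0] == 2:
            day[lo:hi, 0] = 1.0

    labels = [f"{c}:t{tau}" for c in conditions for tau in range(window)]
    labels += ["day2"] + [f"day{d}_scan{s}" for d, s in runs]
    matrix = np.hstack([fir, day, scans])
    return FirDesign(
        matrix=matrix,
        labels=labels,
        conditions=conditions,
        window=window,
        n_frames_per_run=n_frames_per_run,
        n_runs=len(runs),
    )


@dataclass
class FirBetas:
    """Per-participant FIR beta estimates, ``betas[condition]`` = regions x window."""

    participant_id: str
    betas: dict[str, np.ndarray]
    window: int
    region_labels: list[str] | None = None
    meta: dict = field(default_factory=dict)


def _check_fir_identified(design: FirDesign) -> None:
    """Raise if any non-empty FIR column is collinear within the design.

    Nuisance-only collinearity (the day indicator lies in the span of the
    scan indicators by construction) is tolerated: those coefficients are
    resolved by the minimum-norm solution and do not affect FIR betas.
    """
    X = design.matrix
    fir = X[:, design.fir_slice]
    nonzero = np.flatnonzero(np.abs(fir).sum(axis=0) > 0)
    if nonzero.size == 0:
        return
    nuis = X[:, design.fir_slice.stop :]
    q, _ = np.linalg.qr(nuis)
    resid = fir[:, nonzero] - q @ (q.T @ fir[:, nonzero])
    rank = np.linalg.matrix_rank(resid)
    if rank < nonzero.size:
        # name the offending columns via pivoted elimination
        _, r = np.linalg.qr(resid)
        diag = np.abs(np.diag(r))
        bad = [design.labels[nonzero[i]] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise np.linalg.LinAlgError(
            f"rank-deficient FIR design; collinear columns: {bad or 'unresolved'}"
        )


def fit_fir(bold: Sequence, design: FirDesign) -> FirBetas:
    """Fit the FIR GLM for one participant over concatenated runs.

    ``bold`` is a sequence of run-level objects with ``data`` (regions x
    frames), ordered to match the design's (day, scan) run layout.  Betas are
    ordinary least squares via the pseudo-inverse; the scan-indicator
    nuisance block plays the role of per-scan intercepts (fixed-effect
    stand-in for a scan random intercept, exact on balanced noiseless data).
    """
    Y = np.hstack([np.asarray(run.data, dtype=float) for run in bold])  # regions x frames
    if Y.shape[1] != design.matrix.shape[0]:
        raise ValueError(
            f"BOLD frames ({Y.shape[1]}) do not match design rows ({design.matrix.shape[0]})"
        )
    if np.isnan(Y).any():
        raise ValueError("NaNs in BOLD data")
    _check_fir_identified(design)
    coef, *_ = np.linalg.lstsq(design.matrix, Y.T, rcond=None)  # regressors x regions
    betas: dict[str, np.ndarray] = {}
    for c, cond in enumerate(design.conditions):
        block = coef[c * design.window : (c + 1) * design.window, :]
        betas[cond] = block.T.copy()
    first = bold[0]
    return FirBetas(
        participant_id=str(getattr(first, "participant_id", "unknown")),
        betas=betas,
        window=design.window,
        region_labels=list(getattr(first, "region_labels", []) or []) or None,
        meta={"n_regressors": design.n_regressors, "n_runs": design.n_runs},
    )


def fit_participant_betas(
    trials: pd.DataFrame,
    bold: Sequence,
    window: int,
    n_frames_per_run: int,
    tr: float = 1.0,
    separate_models: bool = False,
) -> FirBetas:
    """Estimate all condition betas for one participant.

    By default a single joint design models every trial type — the three
    correct-difficulty blocks, Hard–Incorrect, and a nuisance FIR block for
    incorrect Easy/Medium trials — so that, with closely packed trials, no
    condition's response leaks into another's betas.  ``separate_models``
    instead fits the difficulty model (correct trials only) and the
    Hard–Incorrect model independently, each with its own day/scan
    nuisance; betas are then biased by overlap with unmodelled trials.
    """
    trials = trials.copy()
    trials["condition"] = label_conditions(trials)
    trials.loc[trials["condition"].isna(), "condition"] = "other-incorrect"
    n_incorrect = int((trials["condition"] == CONDITION_HARD_INCORRECT).sum())

    if separate_models:
        design_diff = build_fir_design(
            trials, CONDITIONS_DIFFICULTY, window, n_frames_per_run, tr
        )
        result = fit_fir(bold, design_diff)
        if n_incorrect > 0:
            design_err = build_fir_design(
                trials, (CONDITION_HARD_INCORRECT,), window, n_frames_per_run, tr
            )
            err = fit_fir(bold, design_err)
            result.betas[CONDITION_HARD_INCORRECT] = err.betas[CONDITION_HARD_INCORRECT]
    else:
        conditions = list(CONDITIONS_DIFFICULTY)
        if n_incorrect > 0:
            conditions.append(CONDITION_HARD_INCORRECT)
        if (trials["condition"] == "other-incorrect").any():
            conditions.append("other-incorrect")
        design = build_fir_design(trials, conditions, window, n_frames_per_run, tr)
        result = fit_fir(bold, design)
        result.betas.pop("other-incorrect", None)
    result.meta["n_hard_incorrect_trials"] = n_incorrect
    return result
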