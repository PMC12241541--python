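"""From-scratch recomputation of the pipeline's checkable design numbers.

Each function regenerates its own inputs with the package defaults and a
caller-supplied seed, runs the relevant pipeline stage, and returns the
measured quantity.  Used by the acceptance test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .behavior_stats import BehaviorFit, fit_accuracy_model, fit_rt_model
from .fir_model import (
    CONDITION_HARD_INCORRECT,
    build_fir_design,
    fit_participant_betas,
    label_conditions,
    response_window,
)
from .parcellation import default_parcellation
from .synthetic_data import (
    GeneratorParams,
    generate_behavior,
    generate_bold,
    generate_trial_schedule,
)
from .temporal_dynamics import delay_table

__all__ = [
    "first_negative_time",
    "hard_incorrect_regressor_count",
    "parcellation_region_count",
    "measurements_per_participant",
    "block_duration_seconds",
    "accuracy_decrement_fit",
    "rt_slope_fit",
    "modal_incorrect_delay",
]


def first_negative_time(trial_duration: float = 3.0, tr: float = 1.0) -> float:
    """Seconds after trial onset at which the boxcar*HRF convolution first
    goes negative (the FIR window is this index + 1 frames)."""
    from .fir_model import HrfSpec

    window = response_window(trial_duration, HrfSpec(tr=tr))
    return (window - 1) * tr


def hard_incorrect_regressor_count(seed: int = 0) -> int:
    """Column count of the Hard–Incorrect FIR design for one participant."""
    params = GeneratorParams(n_participants=1, seed=seed)
    trials = generate_behavior(generate_trial_schedule(params), params)
    trials["condition"] = label_conditions(trials)
    window = response_window(params.trial_duration)
    design = build_fir_design(
        trials, (CONDITION_HARD_INCORRECT,), window, params.n_frames_per_run
    )
    return design.n_regressors


def parcellation_region_count() -> int:
    return len(default_parcellation())


def measurements_per_participant(seed: int = 0) -> int:
    """Task blocks per participant in the default two-day schedule."""
    params = GeneratorParams(n_participants=1, seed=seed)
    schedule = generate_trial_schedule(params)
    return len(schedule.groupby(["day", "scan"]))


def block_duration_seconds() -> int:
    """Scheduled duration of one block, rounded to the nearest second."""
    params = GeneratorParams()
    schedule = generate_trial_schedule(params, n_runs=1)
    last = schedule.iloc[-1]
    return int(round(float(last["onset"] + last["duration"] + params.iti)))


def accuracy_decrement_fit(seed: int) -> BehaviorFit:
    """Accuracy mixed model on default study-scale synthetic behaviour."""
    params = GeneratorParams(seed=seed)
    trials = generate_behavior(generate_trial_schedule(params), params)
    return fit_accuracy_model(trials)


def rt_slope_fit(seed: int) -> BehaviorFit:
    """RT mixed model (correct trials) on default study-scale behaviour."""
    params = GeneratorParams(seed=seed)
    trials = generate_behavior(generate_trial_schedule(params), params)
    return fit_rt_model(trials)


def modal_incorrect_delay(seed: int, n_participants: int = 24) -> float:
    """Modal peak cross-correlation lag (s) between Hard–Correct and
    Hard–Incorrect FIR time courses over the delayed-designated regions."""
    params = GeneratorParams(n_participants=n_participants, seed=seed)
    trials = generate_behavior(generate_trial_schedule(params), params)
    runs = generate_bold(trials, params)
    window = response_window(params.trial_duration)
    by_pid: dict[str, list] = {}
    for run in runs:
        by_pid.setdefault(run.participant_id, []).append(run)
    all_betas = []
    for pid, pruns in sorted(by_pid.items()):
        pruns.sort(key=lambda r: (r.day, r.scan))
        ptrials = trials[trials["participant_id"] == pid]
        all_betas.append(
            fit_participant_betas(ptrials, pruns, window, params.n_frames_per_run)
        )
    results = delay_table(
        all_betas,
        ("hard-correct", CONDITION_HARD_INCORRECT),
        params.region_roles().delayed_indices,
        tr=params.tr,
    )
    lags = np.array([r.peak_lag for r in results])
    values, counts = np.unique(lags, return_counts=True)
    return float(values[np.argmax(counts)])
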