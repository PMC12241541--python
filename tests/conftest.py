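import numpy as np
import pytest

from wm_dynamics.fir_model import fit_participant_betas, response_window
from wm_dynamics.synthetic_data import (
    GeneratorParams,
    generate_behavior,
    generate_bold,
    generate_trial_schedule,
)


def fit_all_participants(trials, runs, window, n_frames, tr=1.0):
    by_pid = {}
    for run in runs:
        by_pid.setdefault(run.participant_id, []).append(run)
    out = []
    for pid, pruns in sorted(by_pid.items()):
        pruns.sort(key=lambda r: (r.day, r.scan))
        ptrials = trials[trials["participant_id"] == pid]
        out.append(fit_participant_betas(ptrials, pruns, window, n_frames, tr))
    return out


@pytest.fixture(scope="session")
def window():
    return response_window(3.0)


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(n_participants=8, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    schedule = generate_trial_schedule(small_params)
    trials = generate_behavior(schedule, small_params)
    runs = generate_bold(trials, small_params)
    return trials, runs


@pytest.fixture(scope="session")
def small_betas(small_dataset, small_params, window):
    trials, runs = small_dataset
    return fit_all_participants(trials, runs, window, small_params.n_frames_per_run)


@pytest.fixture(scope="session")
def small_latent(small_betas):
    from wm_dynamics.latent_axes import fit_pca, stack_betas, zscore_timepoints

    conditions = ["easy-correct", "medium-correct", "hard-correct", "hard-incorrect"]
    stack = stack_betas(small_betas, conditions)
    return fit_pca(zscore_timepoints(stack), n_max=40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
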