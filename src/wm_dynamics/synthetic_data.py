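"""Synthetic task schedules, behaviour and parcellated BOLD time series.

Emulates a two-day, eight-scans-per-day working-memory-manipulation design:
each scan contains one 35 s block (5 s instruction + 9 trials of 3 s with a
0.33 s inter-trial interval, 3 trials per difficulty level).  Behaviour
follows a linear-probability accuracy model and a linear response-time
model; BOLD responses are HRF-shaped impulses whose amplitude scales with
difficulty, with a configurable subset of regions responding late on
incorrect trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .fir_model import HrfSpec, trial_response_shape
from .parcellation import default_parcellation

__all__ = [
    "RegionRoles",
    "GeneratorParams",
    "ParcellatedBold",
    "default_region_roles",
    "generate_trial_schedule",
    "generate_behavior",
    "generate_bold",
    "generate_dataset",
]


@dataclass(frozen=True)
class RegionRoles:
    """Ground-truth roles of responsive regions.

    Parallel arrays over responsive regions: atlas index, response sign,
    per-difficulty-level amplitude gain, and whether the region's response
    is delayed on incorrect trials.
    """

    indices: np.ndarray
    signs: np.ndarray
    gains: np.ndarray
    delayed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.indices)
        if not (len(self.signs) == len(self.gains) == len(self.delayed) == n):
            raise ValueError("RegionRoles arrays must have equal length")

    @property
    def delayed_indices(self) -> np.ndarray:
        return self.indices[self.delayed]


def default_region_roles(n_regions: int = 482) -> RegionRoles:
    """80 responsive regions: 60 positive (first 40 delayed on errors), 20 negative."""
    n_pos, n_neg = 60, 20
    indices = np.arange(n_pos + n_neg)
    signs = np.where(indices < n_pos, 1.0, -1.0)
    gains = np.full(n_pos + n_neg, 0.5)
    delayed = indices < 40
    if indices.max() >= n_regions:
        raise ValueError("default roles require n_regions >= 80")
    return RegionRoles(indices=indices, signs=signs, gains=gains, delayed=delayed)


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic dataset, with study-calibrated defaults."""

    n_participants: int = 24
    n_regions: int = 482
    n_days: int = 2
    n_scans_per_day: int = 8
    tr: float = 1.0
    instruction_duration: float = 5.0
    trial_duration: float = 3.0
    iti: float = 0.33
    trials_per_difficulty: int = 3
    accuracy_base: float = 0.95
    accuracy_decrement: float = 0.09
    rt_base: float = 1.3
    rt_slope: float = 0.26
    rt_sd: float = 0.3
    incorrect_delay: float = 3.0
    noise_sd: float = 1.0
    response_frames: int = 15
    n_frames_per_run: int = 50
    roles: RegionRoles | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_regions < 1:
            raise ValueError("counts must be positive")
        worst = self.accuracy_base - 2 * self.accuracy_decrement
        if not (0.0 < worst < 1.0) or not (0.0 < self.accuracy_base <= 1.0):
            raise ValueError("accuracy parameters leave (0, 1) at the hardest level")
        if self.incorrect_delay < 0:
            raise ValueError("incorrect_delay must be non-negative")
        ratio = self.incorrect_delay / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("incorrect_delay must be an integer multiple of tr")
        if self.noise_sd < 0 or self.rt_sd < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def n_runs(self) -> int:
        return self.n_days * self.n_scans_per_day

    @property
    def n_trials_per_block(self) -> int:
        return 3 * self.trials_per_difficulty

    @property
    def block_duration(self) -> float:
        # trailing ITI included in the scheduled trial period
        return self.instruction_duration + self.n_trials_per_block * (
            self.trial_duration + self.iti
        )

    def region_roles(self) -> RegionRoles:
        return self.roles if self.roles is not None else default_region_roles(self.n_regions)

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass
class ParcellatedBold:
    """One run of parcellated BOLD: ``data`` is regions x frames."""

    participant_id: str
    day: int
    scan: int
    data: np.ndarray
    tr: float
    region_labels: list[str] = field(default_factory=list)
    region_groups: list[str] = field(default_factory=list)


def _participant_ids(params: GeneratorParams) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(params.n_participants)]


def generate_trial_schedule(
    params: GeneratorParams = GeneratorParams(), n_runs: int | None = None
) -> pd.DataFrame:
    """Seeded trial schedule shared by all participants.

    One row per trial with ``day``, ``scan``, ``trial_index`` (1-based),
    ``onset`` (s from run start), ``duration`` and ``difficulty`` (0/1/2).
    The difficulty order of each run is an independent seeded permutation of
    three trials per level; it is common to all participants.
    """
    if n_runs is None:
        n_runs = params.n_runs
    if n_runs < 0:
        raise ValueError("n_runs must be non-negative")
    rng = np.random.default_rng(params.seed)
    base = np.repeat(np.arange(3), params.trials_per_difficulty)
    rows = []
    for run in range(n_runs):
        order = rng.permutation(base)
        day = run // params.n_scans_per_day + 1
        scan = run % params.n_scans_per_day + 1
        for i, diff in enumerate(order):
            onset = params.instruction_duration + i * (params.trial_duration + params.iti)
            rows.append((day, scan, i + 1, onset, params.trial_duration, int(diff)))
    return pd.DataFrame(
        rows, columns=["day", "scan", "trial_index", "onset", "duration", "difficulty"]
    )


def generate_behavior(
    schedule: pd.DataFrame, params: GeneratorParams = GeneratorParams()
) -> pd.DataFrame:
    """Expand a shared schedule to per-participant trials with behaviour.

    Correctness is Bernoulli with P(correct) = base − decrement·difficulty
    (clipped to [0, 1]); response time is base + slope·difficulty plus
    truncated-normal noise confined to (0, trial duration].
    """
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(params.seed + 1)
    frames = []
    for pid in _participant_ids(params):
        trials = schedule.copy()
        trials.insert(0, "participant_id", pid)
        diff = trials["difficulty"].to_numpy()
        p_correct = np.clip(
            params.accuracy_base - params.accuracy_decrement * diff, 0.0, 1.0
        )
        trials["correct"] = rng.random(len(trials)) < p_correct
        mu = params.rt_base + params.rt_slope * diff
        hi = trials["duration"].to_numpy()
        if params.rt_sd == 0:
            rt = np.minimum(mu, hi)
        else:
            a = (0.0 - mu) / params.rt_sd
            b = (hi - mu) / params.rt_sd
            rt = truncnorm.rvs(a, b, loc=mu, scale=params.rt_sd, random_state=rng)
        trials["response_time"] = rt
        frames.append(trials)
    return pd.concat(frames, ignore_index=True)


def generate_bold(
    trials: pd.DataFrame, params: GeneratorParams = GeneratorParams()
) -> list[ParcellatedBold]:
    """Synthesise parcellated BOLD runs for every participant in ``trials``.

    Each trial adds, to every responsive region, the boxcar-convolved HRF
    shape (truncated to ``response_frames``) scaled by
    sign · (1 + gain · difficulty), injected at the trial's onset frame.
    On incorrect trials the delayed subset responds ``incorrect_delay``
    seconds late.  I.i.d. Gaussian noise (``noise_sd``) is added everywhere;
    non-responsive regions are pure baseline (zero mean) plus noise.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    roles = params.region_roles()
    if roles.indices.size and roles.indices.max() >= params.n_regions:
        raise ValueError("responsive region index exceeds n_regions")
    delay_frames = int(round(params.incorrect_delay / params.tr))
    shape = trial_response_shape(
        params.trial_duration,
        HrfSpec(tr=params.tr),
        n_frames=params.response_frames,
    )
    parcels = default_parcellation() if params.n_regions == 482 else None
    labels = (
        list(parcels["label"])
        if parcels is not None
        else [f"region_{i + 1:03d}" for i in range(params.n_regions)]
    )
    groups = (
        list(parcels["group"])
        if parcels is not None
        else ["none"] * params.n_regions
    )

    rng = np.random.default_rng(params.seed + 2)
    runs: list[ParcellatedBold] = []
    for pid, ptrials in trials.groupby("participant_id", sort=True):
        for (day, scan), rtrials in ptrials.groupby(["day", "scan"], sort=True):
            data = (
                rng.normal(0.0, params.noise_sd, (params.n_regions, params.n_frames_per_run))
                if params.noise_sd > 0
                else np.zeros((params.n_regions, params.n_frames_per_run))
            )
            for _, trial in rtrials.iterrows():
                onset_frame = int(round(float(trial["onset"]) / params.tr))
                amp = 1.0 + roles.gains * float(trial["difficulty"])
                for j, region in enumerate(roles.indices):
                    start = onset_frame
                    if not bool(trial["correct"]) and roles.delayed[j]:
                        start += delay_frames
                    stop = min(start + len(shape), params.n_frames_per_run)
                    if start >= stop:
                        continue
                    data[region, start:stop] += roles.signs[j] * amp[j] * shape[: stop - start]
            runs.append(
                ParcellatedBold(
                    participant_id=str(pid),
                    day=int(day),
                    scan=int(scan),
                    data=data,
                    tr=params.tr,
                    region_labels=labels,
                    region_groups=groups,
                )
            )
    return runs


def generate_dataset(
    params: GeneratorParams = GeneratorParams(),
) -> tuple[pd.DataFrame, list[ParcellatedBold]]:
    """Full synthetic dataset: per-participant trials and BOLD runs."""
    schedule = generate_trial_schedule(params)
    trials = generate_behavior(schedule, params)
    return trials, generate_bold(trials, params)
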