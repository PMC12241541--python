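"""Lagged cross-correlation between condition time courses and the
probability/energy landscape of time-resolved BOLD amplitude."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "cross_correlate",
    "detect_delay",
    "DelayResult",
    "delay_table",
    "EnergyLandscape",
    "energy_landscape",
    "density_mass",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def cross_correlate(x: np.ndarray, y: np.ndarray, max_lag: int = 7) -> np.ndarray:
    """Pearson correlation of overlapping segments at integer lags −L..L.

    At lag s >= 0 the correlation pairs x[t] with y[t + s]: a positive peak
    lag means y is a delayed copy of x.  Each lag is normalised on its own
    overlap (no zero padding).  Zero-variance overlaps give NaN for that
    lag.  Returns an array of length 2·max_lag + 1 indexed by lag + max_lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < max_lag + 2:
        raise ValueError("series too short for requested max_lag (need >= 2 overlap points)")
    ccf = np.full(2 * max_lag + 1, np.nan)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[: len(x) - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: len(y) + lag]
        if a.std() == 0 or b.std() == 0:
            continue
        ccf[lag + max_lag] = np.corrcoef(a, b)[0, 1]
    return ccf


@dataclass
class DelayResult:
    region_label: str
    ccf: np.ndarray
    max_lag: int
    peak_lag: float  # seconds
    peak_r: float
    delayed: bool


def detect_delay(
    ccf: np.ndarray,
    tr: float = 1.0,
    threshold_lag: int = 1,
    region_label: str = "",
) -> DelayResult:
    """Locate the peak-correlation lag and flag positive delays.

    Ties are resolved to the smallest |lag|, then to the positive sign.
    ``delayed`` requires a positive peak correlation at a lag of at least
    ``threshold_lag`` frames.
    """
    ccf = np.asarray(ccf, dtype=float)
    if np.isnan(ccf).all():
        raise ValueError("all lags undefined")
    max_lag = (len(ccf) - 1) // 2
    lags = np.arange(-max_lag, max_lag + 1)
    best = np.nanmax(ccf)
    cand = lags[ccf == best]
    # smallest magnitude first, positive before negative on magnitude ties
    cand = sorted(cand, key=lambda s: (abs(s), -np.sign(s)))
    peak = int(cand[0])
    return DelayResult(
        region_label=region_label,
        ccf=ccf,
        max_lag=max_lag,
        peak_lag=peak * tr,
        peak_r=float(best),
        delayed=bool(peak >= threshold_lag and best > 0),
    )


def delay_table(
    all_betas,
    condition_pair: tuple[str, str],
    region_indices: np.ndarray,
    max_lag: int = 7,
    tr: float = 1.0,
    threshold_lag: int = 1,
):
    """Per-region delay detection on participant-mean FIR time courses.

    The two condition time courses are averaged across the participants
    that have both conditions, then cross-correlated per region.  Returns a
    list of :class:`DelayResult`.
    """
    c0, c1 = condition_pair
    xs, ys = [], []
    for fb in all_betas:
        if c0 in fb.betas and c1 in fb.betas:
            xs.append(fb.betas[c0])
            ys.append(fb.betas[c1])
    if not xs:
        raise ValueError("no participant has both conditions")
    X = np.mean(xs, axis=0)
    Y = np.mean(ys, axis=0)
    labels = next(iter(all_betas)).region_labels
    results = []
    for r in region_indices:
        label = labels[r] if labels else f"region_{r + 1:03d}"
        ccf = cross_correlate(X[r], Y[r], max_lag=max_lag)
        results.append(detect_delay(ccf, tr=tr, threshold_lag=threshold_lag, region_label=label))
    return results


@dataclass
class EnergyLandscape:
    """Per-timepoint KDE probability and energy over an |BOLD| grid.

    ``P`` and ``E`` are grid x timepoints; ``E = -ln(P)`` with ``inf``
    where the density vanishes.
    """

    grid: np.ndarray
    P: np.ndarray
    E: np.ndarray
    bandwidth: float
    n_samples: np.ndarray
    meta: dict = field(default_factory=dict)


def _kde(samples: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian-kernel density 1/(h n) Σ K((x − xᵢ)/h) on ``grid``."""
    z = (grid[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z**2).sum(axis=1) / (h * len(samples) * _SQRT2PI)


def energy_landscape(
    samples_per_timepoint: list[np.ndarray],
    grid_max: float = 1.8,
    grid_step: float = 0.01,
    bandwidth: float = 0.1,
) -> EnergyLandscape:
    """Energy landscape of |BOLD| amplitude across timepoints.

    ``samples_per_timepoint[t]`` pools absolute beta values over regions and
    participants at timepoint t.  The density is a Gaussian KDE with
    bandwidth ``h`` evaluated on a grid over [0, grid_max]; energy is the
    negative natural log of the density (infinite where the density is 0).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_max <= 0 or grid_step <= 0:
        raise ValueError("grid must be positive")
    grid = np.arange(0.0, grid_max + grid_step / 2, grid_step)
    T = len(samples_per_timepoint)
    P = np.empty((len(grid), T))
    n = np.empty(T, dtype=int)
    for t, raw in enumerate(samples_per_timepoint):
        s = np.abs(np.asarray(raw, dtype=float)).ravel()
        if s.size < 2:
            raise ValueError(f"timepoint {t + 1}: need >= 2 samples")
        n[t] = s.size
        P[:, t] = _kde(s, grid, bandwidth)
    with np.errstate(divide="ignore"):
        E = -np.log(P)
    return EnergyLandscape(grid=grid, P=P, E=E, bandwidth=bandwidth, n_samples=n)


def landscape_from_betas(
    all_betas, condition: str, region_indices: np.ndarray, **kwargs
) -> EnergyLandscape:
    """Pool |betas| over participants and a region set per timepoint."""
    per_t: list[list[float]] = None
    for fb in all_betas:
        if condition not in fb.betas:
            continue
        block = fb.betas[condition][region_indices, :]
        if per_t is None:
            per_t = [[] for _ in range(block.shape[1])]
        for t in range(block.shape[1]):
            per_t[t].extend(np.abs(block[:, t]))
    if per_t is None:
        raise ValueError(f"no participant has condition {condition!r}")
    return energy_landscape([np.asarray(s) for s in per_t], **kwargs)


def density_mass(
    samples: np.ndarray, bandwidth: float = 0.1, grid_step: float = 0.01, pad: float = 6.0
) -> float:
    """Numerical integral of the KDE over a grid extended past the samples.

    Extends ``pad`` bandwidths beyond the sample range so the full kernel
    mass is captured; used to verify the estimator integrates to ~1.
    """
    s = np.asarray(samples, dtype=float).ravel()
    lo = s.min() - pad * bandwidth
    hi = s.max() + pad * bandwidth
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    z = (grid[:, None] - s[None, :]) / bandwidth
    P = np.exp(-0.5 * z**2).sum(axis=1) / (bandwidth * len(s) * _SQRT2PI)
    return float(P.sum() * grid_step)
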