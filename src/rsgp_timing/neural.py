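"""Synthetic population spike counts and decoding of the behavioral drift.

The generator plants a known 'drift direction' in a population of Poisson
neurons: the log firing rate of neuron i on trial n is

    log(lambda_in) = log(baseline) + b_i * (gain * e_slow_n + eta_n) + o_i * u_n

where b is the (unit-norm) planted direction, e_slow the slow component of the
behavioral error series, eta a shared latent noise along b, o a direction
orthogonal to b, and u an independent shared latent.  Two coupling profiles
mirror the two qualitative regimes observed across brain areas:

* ``thalamus_like`` — the shared noise *along the planted direction* (eta) is
  scaled up after unrewarded and down after rewarded trials, so variability
  along the drift direction is reward-regulated;
* ``cortex_like`` — the same reward-scaling is applied to the orthogonal
  latent (u) instead, so reward modulates population variability but not
  along the drift direction.

Decoding follows the cross-validated multi-linear regression recipe: fit
e_slow ~ counts * beta + beta0 on a random half of trials, project held-out
spike counts onto beta to obtain z, and compare the held-out Pearson
correlation against a trial-shuffle null.  The z series is then analyzed with
the same mean/variance-vs-previous-error machinery used for behavior.

All spike counts here are synthetic stand-ins for recordings; no real
electrophysiology is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import ErrorStats, error_stats_by_prev

__all__ = [
    "SpikeCountMatrix",
    "DriftFit",
    "synth_spike_counts",
    "fit_drift_direction",
    "z_stats_by_prev_error",
]


@dataclass
class SpikeCountMatrix:
    """trials x neurons matrix of non-negative integer spike counts."""

    counts: np.ndarray
    window_ms: float = 250.0
    alignment: str = "Set"
    planted_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be trials x neurons")
        if (c < 0).any():
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]


@dataclass
class DriftFit:
    """Cross-validated linear decode of a behavioral target from spike counts."""

    beta: np.ndarray
    beta0: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    z: np.ndarray  # projection for every trial (train and test)
    r_heldout: float
    null_quantiles: tuple[float, float]  # 1% / 99% of the shuffle null
    ridge_penalty: float = 0.0

    @property
    def significant(self) -> bool:
        return self.r_heldout > self.null_quantiles[1]


def synth_spike_counts(
    e_slow: Sequence[float],
    reward_history: Sequence[bool],
    n_neurons: int = 17,
    planted_beta: Sequence[float] | None = None,
    gain: float = 5.0,
    variance_coupling: str = "thalamus_like",
    baseline_rate: float = 10.0,
    shared_noise_sd: float = 0.35,
    reward_scale: tuple[float, float] = (0.5, 1.6),
    rng: np.random.Generator | None = None,
) -> SpikeCountMatrix:
    """Poisson population whose projection on a planted direction tracks
    the slow behavioral drift.

    ``reward_history[n]`` is the outcome of trial n; the shared-noise SD on
    trial n is scaled by ``reward_scale[0]`` if trial n-1 was rewarded and by
    ``reward_scale[1]`` otherwise (the first trial uses the geometric mean).
    ``gain`` converts e_slow (relative-error units, SD ~ 0.1) into log-rate
    drive; the defaults put mean counts in the 5-20 per-window range.
    """
    if variance_coupling not in ("thalamus_like", "cortex_like"):
        raise ValueError(f"unknown variance_coupling {variance_coupling!r}")
    rng = rng or np.random.default_rng(0)
    es = np.asarray(e_slow, dtype=float)
    rew = np.asarray(reward_history, dtype=bool)
    if es.size != rew.size:
        raise ValueError("e_slow and reward_history must have equal length")
    n = es.size

    if planted_beta is None:
        b = rng.standard_normal(n_neurons)
    else:
        b = np.asarray(planted_beta, dtype=float)
        if b.size != n_neurons:
            raise ValueError("planted_beta length must equal n_neurons")
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("planted_beta must be non-zero")
    b = b / nb
    # any unit vector orthogonal to b
    o = rng.standard_normal(n_neurons)
    o -= (o @ b) * b
    o /= np.linalg.norm(o)

    scale = np.empty(n)
    scale[0] = np.sqrt(reward_scale[0] * reward_scale[1])
    scale[1:] = np.where(rew[:-1], reward_scale[0], reward_scale[1])

    if variance_coupling == "thalamus_like":
        eta = shared_noise_sd * scale * rng.standard_normal(n)
        u = shared_noise_sd * rng.standard_normal(n)
    else:
        eta = shared_noise_sd * rng.standard_normal(n)
        u = shared_noise_sd * scale * rng.standard_normal(n)

    drive = gain * (es - es.mean()) + eta
    log_rate = np.log(baseline_rate) + np.outer(drive, b) + np.outer(u, o)
    counts = rng.poisson(np.exp(np.clip(log_rate, -30, 30)))
    return SpikeCountMatrix(counts=counts, planted_beta=b)


def fit_drift_direction(
    spikes: SpikeCountMatrix,
    target: Sequence[float],
    split_seed: int = 0,
    n_shuffles: int = 100,
    ridge: float | None = None,
    sqrt_transform: bool = False,
) -> DriftFit:
    """Least-squares decode of ``target`` from spike counts, cross-validated
    on a random half split, with a trial-shuffle null for the held-out
    Pearson correlation.

    Plain least squares is used when trials >= 4x neurons; otherwise (or when
    the design is rank-deficient) a small ridge penalty is applied.
    ``sqrt_transform`` square-roots the counts first (variance stabilization
    for Poisson-like counts).
    """
    y = np.asarray(target, dtype=float)
    X = np.asarray(spikes.counts, dtype=float)
    if sqrt_transform:
        X = np.sqrt(X)
    n, p = X.shape
    if y.size != n:
        raise ValueError("target must align with trials")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    train, test = np.sort(perm[: n // 2]), np.sort(perm[n // 2 :])

    lam = ridge
    if lam is None:
        lam = 0.0 if len(train) >= 4 * p else _ridge_by_cv(X[train], y[train], rng)

    def solve(Xtr: np.ndarray, ytr: np.ndarray) -> tuple[np.ndarray, float]:
        A = np.column_stack([Xtr, np.ones(len(Xtr))])
        if lam > 0:
            P = lam * np.eye(p + 1)
            P[-1, -1] = 0.0  # do not penalize the intercept
            coef = np.linalg.solve(A.T @ A + P, A.T @ ytr)
        else:
            coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        return coef[:-1], float(coef[-1])

    try:
        beta, beta0 = solve(X[train], y[train])
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient design; refitting with ridge", stacklevel=2)
        lam = max(lam, 1.0)
        beta, beta0 = solve(X[train], y[train])

    z = X @ beta + beta0
    r = _pearson(z[test], y[test])

    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        ys = rng.permutation(y)
        b_s, b0_s = solve(X[train], ys[train])
        null[i] = _pearson(X[test] @ b_s + b0_s, ys[test])
    q01, q99 = np.quantile(null, [0.01, 0.99])

    return DriftFit(
        beta=beta,
        beta0=beta0,
        train_idx=train,
        test_idx=test,
        z=z,
        r_heldout=r,
        null_quantiles=(float(q01), float(q99)),
        ridge_penalty=lam,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _ridge_by_cv(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> float:
    """Pick the ridge penalty by a single held-in split over a log grid."""
    n = len(X)
    perm = rng.permutation(n)
    a, b = perm[: n // 2], perm[n // 2 :]
    best_lam, best_r = 1.0, -np.inf
    p = X.shape[1]
    for lam in (0.1, 1.0, 10.0, 100.0):
        A = np.column_stack([X[a], np.ones(len(a))])
        P = lam * np.eye(p + 1)
        P[-1, -1] = 0.0
        coef = np.linalg.solve(A.T @ A + P, A.T @ y[a])
        r = _pearson(X[b] @ coef[:-1] + coef[-1], y[b])
        if r > best_r:
            best_lam, best_r = lam, r
    return best_lam


def z_stats_by_prev_error(
    z: Sequence[float],
    pairs: pd.DataFrame,
    n_bins: int = 10,
    **kwargs,
) -> ErrorStats:
    """Mean/SD of the population projection z^n vs previous-trial error.

    ``pairs`` comes from :func:`rsgp_timing.stats.pair_trials`; z^n replaces
    e^n while e^{n-1} stays behavioral, so the identical binning/regression
    machinery applies.
    """
    z = np.asarray(z, dtype=float)
    zpairs = pairs.copy()
    zpairs["e_next"] = z[pairs["next_pos"].to_numpy(dtype=int)]
    return error_stats_by_prev(zpairs, n_bins=n_bins, **kwargs)
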