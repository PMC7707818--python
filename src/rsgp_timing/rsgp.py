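"""Reward-sensitive Gaussian process (RSGP) for trial series of timing errors.

The relative-error series e^1..e^N of one trial type is modelled as a zero-mean
(after centering) Gaussian process whose covariance between trials n and n-r is

    K_RSGP(n, n-r) = sigma_SE^2 * K_SE(n, n-r) + sigma_RS^2 * K_RS(n, n-r)
                     + sigma_0^2 * I

with a slow squared-exponential kernel K_SE(r) = exp(-r^2 / (2 l_SE^2))
(memory drift: long-range serial correlations) and a reward-gated kernel whose
off-diagonal term exp(-r^2 / (2 l_RS^2)) is present only if the earlier trial
n-r was rewarded (exploitation: rewarded trials constrain the near future,
unrewarded trials release variability).  Reward is binary here even when the
task pays graded reward.

The module provides kernel construction, sequential forward generation, the
Gaussian log marginal likelihood with analytic gradients, the two-step
maximum-marginal-likelihood fit (slow kernel on unrewarded trials first, then
all five hyperparameters jointly), and the posterior decomposition of an
observed series into slow (e_slow) and fast residual components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize

from .task import Context, Effector, IntervalClass, SessionData, TrialRecord

__all__ = [
    "RSGPParams",
    "CovMatrix",
    "SlowFastDecomposition",
    "k_se",
    "build_cov",
    "sample_next",
    "forward_simulate",
    "log_marginal_likelihood",
    "fit_mml",
    "infer_e_slow",
    "RSGPAgent",
    "TABLE_GROUND_TRUTH",
]

_JITTER_FRAC = 1e-8

#: Hyperparameters used throughout as the reference simulation condition
#: (l_SE, sigma_SE, l_RS, sigma_RS, sigma_0).
TABLE_GROUND_TRUTH: tuple[float, float, float, float, float] = (20.0, 0.141, 2.0, 0.141, 0.10)


@dataclass(frozen=True)
class RSGPParams:
    """The five RSGP hyperparameters.

    Length scales are in units of (within-context) trials; variances are in
    relative-error units.
    """

    l_se: float
    sigma_se: float
    l_rs: float
    sigma_rs: float
    sigma_0: float

    def __post_init__(self) -> None:
        if self.l_se <= 0 or self.l_rs <= 0:
            raise ValueError("length scales must be positive")
        if min(self.sigma_se, self.sigma_rs, self.sigma_0) < 0:
            raise ValueError("kernel amplitudes must be non-negative")
        if self.sigma_se == self.sigma_rs == self.sigma_0 == 0:
            raise ValueError("at least one variance component must be positive")

    @property
    def total_variance(self) -> float:
        return self.sigma_se**2 + self.sigma_rs**2 + self.sigma_0**2

    def as_array(self) -> np.ndarray:
        return np.array([self.l_se, self.sigma_se, self.l_rs, self.sigma_rs, self.sigma_0])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "RSGPParams":
        return cls(*(float(x) for x in a))


@dataclass
class CovMatrix:
    """Trial covariance built from a reward history."""

    values: np.ndarray
    reward_mask: np.ndarray

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def k_se(r, l_se: float):
    """Squared-exponential correlation at trial lag r: exp(-r^2 / (2 l^2))."""
    if l_se <= 0:
        raise ValueError("l_se must be positive")
    r = np.asarray(r, dtype=float)
    out = np.exp(-(r**2) / (2.0 * l_se**2))
    return float(out) if out.ndim == 0 else out


def _rs_kernel(n: int, l_rs: float, rewarded: np.ndarray) -> np.ndarray:
    """Reward-gated kernel: off-diagonal (i, j) is exp(-(i-j)^2/(2 l_RS^2))
    iff the earlier of the two trials was rewarded; the diagonal is 1 (a
    trial's own reward is unknown when it is generated, so the gate applies
    only to past-trial cross-covariances)."""
    idx = np.arange(n)
    lags = idx[:, None] - idx[None, :]
    k = np.exp(-(lags.astype(float) ** 2) / (2.0 * l_rs**2))
    earlier = np.minimum(idx[:, None], idx[None, :])
    gate = rewarded[earlier].astype(float)
    np.fill_diagonal(gate, 1.0)
    return k * gate


def build_cov(params: RSGPParams, reward_history: Sequence[bool]) -> CovMatrix:
    """K = sigma_SE^2 K_SE + sigma_RS^2 K_RS + sigma_0^2 I for n trials."""
    rewarded = np.asarray(reward_history, dtype=bool)
    n = rewarded.size
    if n < 1:
        raise ValueError("need at least one trial")
    lags = np.subtract.outer(np.arange(n), np.arange(n))
    K = (
        params.sigma_se**2 * k_se(lags, params.l_se)
        + params.sigma_rs**2 * _rs_kernel(n, params.l_rs, rewarded)
        + params.sigma_0**2 * np.eye(n)
    )
    return CovMatrix(values=K, reward_mask=rewarded)


def _chol_jitter(K: np.ndarray) -> np.ndarray:
    """Cholesky with escalating diagonal jitter (the reward gating is not
    guaranteed PSD for adversarial reward patterns)."""
    jitter = _JITTER_FRAC * float(np.mean(np.diag(K)))
    for _ in range(4):
        try:
            return linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter *= 10.0
    raise linalg.LinAlgError("covariance not positive definite after jitter")


def _cross_cov(params: RSGPParams, n_hist: int, rewarded_hist: np.ndarray) -> np.ndarray:
    """Covariance between the next trial and each of the n_hist past trials."""
    r = np.arange(n_hist, 0, -1, dtype=float)  # lag to each past trial
    k = params.sigma_se**2 * k_se(r, params.l_se)
    k = k + params.sigma_rs**2 * k_se(r, params.l_rs) * rewarded_hist.astype(float)
    return k


def sample_next(
    history_e: Sequence[float],
    reward_history: Sequence[bool],
    params: RSGPParams,
    rng: np.random.Generator,
    mean: float = 0.0,
) -> tuple[float, float, float]:
    """Conditional distribution of the next trial's error given the history.

    Returns ``(mean, variance, sample)``.  With an empty history the prior
    marginal applies: variance sigma_SE^2 + sigma_RS^2 + sigma_0^2.
    """
    e = np.asarray(history_e, dtype=float)
    rew = np.asarray(reward_history, dtype=bool)
    if e.size != rew.size:
        raise ValueError("history_e and reward_history must have equal length")
    prior_var = params.total_variance
    if e.size == 0:
        mu, var = mean, prior_var
    else:
        K = build_cov(params, rew).values
        L = _chol_jitter(K)
        k = _cross_cov(params, e.size, rew)
        y = linalg.solve_triangular(L, k, lower=True)
        w = linalg.solve_triangular(L, e - mean, lower=True)
        mu = mean + float(y @ w)
        var = max(prior_var - float(y @ y), 1e-12)
    sample = mu + np.sqrt(var) * rng.standard_normal()
    return mu, var, float(sample)


class _SequentialRSGP:
    """Incremental-Cholesky sequential sampler (O(n^2) per appended trial)."""

    def __init__(self, params: RSGPParams, capacity: int, mean: float = 0.0):
        self.params = params
        self.mean = mean
        self.L = np.zeros((capacity, capacity))
        self.w = np.zeros(capacity)  # L^-1 (e - mean)
        self.e = np.zeros(capacity)
        self.rewarded = np.zeros(capacity, dtype=bool)
        self.n = 0
        self._jitter = _JITTER_FRAC * params.total_variance

    def next_moments(self) -> tuple[float, float, np.ndarray]:
        p, n = self.params, self.n
        prior_var = p.total_variance + self._jitter
        if n == 0:
            return self.mean, prior_var, np.empty(0)
        k = _cross_cov(p, n, self.rewarded[:n])
        y = linalg.solve_triangular(self.L[:n, :n], k, lower=True, check_finite=False)
        mu = self.mean + float(y @ self.w[:n])
        var = max(prior_var - float(y @ y), 1e-12)
        return mu, var, y

    def append(self, e_new: float, rewarded: bool, y: np.ndarray) -> None:
        n = self.n
        prior_var = self.params.total_variance + self._jitter
        d = np.sqrt(max(prior_var - float(y @ y), 1e-12))
        self.L[n, :n] = y
        self.L[n, n] = d
        self.w[n] = (e_new - self.mean - float(y @ self.w[:n])) / d
        self.e[n] = e_new
        self.rewarded[n] = rewarded
        self.n = n + 1


class RSGPAgent:
    """Task agent generating t_p = t_t * (1 + e) with e drawn sequentially
    from the RSGP conditioned on this context's own history."""

    def __init__(self, context: Context, params: RSGPParams, capacity: int = 4096):
        self.context = context
        self.params = params
        self._gp = _SequentialRSGP(params, capacity)
        self._pending_y: np.ndarray | None = None
        self._pending_e: float | None = None

    def next_tp(self, rng: np.random.Generator) -> float:
        mu, var, y = self._gp.next_moments()
        e = mu + np.sqrt(var) * rng.standard_normal()
        self._pending_y, self._pending_e = y, float(e)
        t_t = self.context.target_interval
        return max(t_t * (1.0 + e), 1.0)

    def observe(self, trial: TrialRecord) -> None:
        if self._pending_y is None:
            raise RuntimeError("observe() called before next_tp()")
        # use the exact e realised by the task (t_p may have been clamped)
        self._gp.append(trial.e, trial.rewarded, self._pending_y)
        self._pending_y = self._pending_e = None


def forward_simulate(
    params: RSGPParams,
    n_trials: int,
    reward_rule: Callable[[float], bool] | None = None,
    seed: int = 0,
    context: Context | None = None,
    window_rel: float = 0.1,
) -> SessionData:
    """Generate a single-context session from the RSGP generative loop.

    Each trial: draw e from the conditional Gaussian given all previous trials
    and their rewards, apply the reward rule, update the reward-gated kernel.
    ``reward_rule`` maps e -> rewarded; by default a fixed acceptance window of
    half-width ``window_rel`` (relative units). For the staircase schedule use
    :func:`rsgp_timing.task.simulate_session` with an :class:`RSGPAgent`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ctx = context or Context(Effector.EYE, IntervalClass.SHORT, 800.0)
    rule = reward_rule if reward_rule is not None else (lambda e: abs(e) < window_rel)
    rng = np.random.default_rng(seed)
    gp = _SequentialRSGP(params, n_trials)
    trials: list[TrialRecord] = []
    t_t = ctx.target_interval
    for n in range(1, n_trials + 1):
        mu, var, y = gp.next_moments()
        e = mu + np.sqrt(var) * rng.standard_normal()
        t_p = max(t_t * (1.0 + e), 1.0)
        e = (t_p - t_t) / t_t
        rewarded = bool(rule(e))
        gp.append(e, rewarded, y)
        trials.append(
            TrialRecord(
                index=n,
                context=ctx,
                t_p=t_p,
                e=e,
                reward_magnitude=0.5 * max(1.0 - abs(e) / window_rel, 0.0) if rewarded else 0.0,
                rewarded=rewarded,
                feedback="correct" if rewarded else "incorrect",
                time_since_prev=0.0 if n == 1 else 3.0,
                window_ms=window_rel * t_t,
            )
        )
    return SessionData(trials=trials, seed=seed, metadata={"generator": "rsgp_forward"})


# ---------------------------------------------------------------------------
# Marginal likelihood and fitting
# ---------------------------------------------------------------------------

def log_marginal_likelihood(
    params: RSGPParams,
    e: Sequence[float],
    reward_history: Sequence[bool],
    center: bool = True,
) -> float:
    """Gaussian log marginal likelihood of the (centered) error series."""
    e = np.asarray(e, dtype=float)
    rew = np.asarray(reward_history, dtype=bool)
    x = e - e.mean() if center else e
    K = build_cov(params, rew).values
    L = _chol_jitter(K)
    alpha = linalg.cho_solve((L, True), x)
    return float(
        -0.5 * x @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * x.size * np.log(2 * np.pi)
    )


def _nll_and_grad(
    log_theta: np.ndarray,
    x: np.ndarray,
    rewarded: np.ndarray,
    free: np.ndarray,
    full_theta: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient w.r.t. log-parameters.

    ``log_theta`` holds the free subset of log(l_SE, s_SE, l_RS, s_RS, s_0);
    fixed entries are taken from ``full_theta``.
    """
    theta = full_theta.copy()
    theta[free] = np.exp(log_theta)
    l_se, s_se, l_rs, s_rs, s_0 = theta
    n = x.size
    idx = np.arange(n)
    lags = (idx[:, None] - idx[None, :]).astype(float)
    sq = lags**2
    Kse = np.exp(-sq / (2.0 * l_se**2))
    Krs = _rs_kernel(n, l_rs, rewarded)
    K = s_se**2 * Kse + s_rs**2 * Krs + (s_0**2) * np.eye(n)
    try:
        L = _chol_jitter(K)
    except linalg.LinAlgError:
        # indefinite reward-gated kernel at extreme hyperparameters: steer
        # the line search back with a large finite penalty
        return 1e10, np.zeros(int(free.sum()))
    alpha = linalg.cho_solve((L, True), x)
    nll = 0.5 * x @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dMLL/dK = 0.5 * A

    # dK/dtheta for each hyperparameter
    dKs = {
        0: s_se**2 * Kse * (sq / l_se**3),
        1: 2.0 * s_se * Kse,
        2: s_rs**2 * _rs_offdiag_dl(n, l_rs, rewarded),
        3: 2.0 * s_rs * Krs,
        4: 2.0 * s_0 * np.eye(n),
    }
    grad = np.empty(int(free.sum()))
    for g, i in enumerate(np.flatnonzero(free)):
        dmll = 0.5 * np.sum(A * dKs[i])
        grad[g] = -dmll * theta[i]  # chain rule through log-parametrization
    return float(nll), grad


def _rs_offdiag_dl(n: int, l_rs: float, rewarded: np.ndarray) -> np.ndarray:
    idx = np.arange(n)
    lags = (idx[:, None] - idx[None, :]).astype(float)
    sq = lags**2
    k = np.exp(-sq / (2.0 * l_rs**2)) * (sq / l_rs**3)
    earlier = np.minimum(idx[:, None], idx[None, :])
    gate = rewarded[earlier].astype(float)
    np.fill_diagonal(gate, 0.0)  # diagonal of K_RS is constant 1
    return k * gate


_L_BOUNDS = (0.5, 500.0)
_S_BOUNDS = (1e-4, 1.0)


def _optimize(
    x: np.ndarray,
    rewarded: np.ndarray,
    init_theta: np.ndarray,
    free: np.ndarray,
) -> tuple[np.ndarray, float]:
    bounds_full = [_L_BOUNDS, _S_BOUNDS, _L_BOUNDS, _S_BOUNDS, _S_BOUNDS]
    lb = np.log([bounds_full[i][0] for i in np.flatnonzero(free)])
    ub = np.log([bounds_full[i][1] for i in np.flatnonzero(free)])
    z0 = np.clip(np.log(init_theta[free]), lb, ub)
    res = optimize.minimize(
        _nll_and_grad,
        z0,
        args=(x, rewarded, free, init_theta),
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": 200},
    )
    theta = init_theta.copy()
    theta[free] = np.exp(res.x)
    return theta, -float(res.fun)


def fit_mml(
    session: SessionData | Sequence[float],
    reward_history: Sequence[bool] | None = None,
    context: Context | str | None = None,
    init: RSGPParams | None = None,
    restarts: int = 3,
    seed: int = 0,
) -> RSGPParams:
    """Two-step maximum-marginal-likelihood fit of the five hyperparameters.

    Step 1 estimates the slow kernel (l_SE, sigma_SE) together with sigma_0 on
    the chronologically ordered subsequence of *unrewarded* trials (where the
    reward-gated kernel contributes nothing off-diagonal), with sigma_RS
    clamped to zero.  Step 2 refines all five hyperparameters on the full
    series by quasi-Newton ascent of the log marginal likelihood from the
    step-1 solution plus ``restarts`` random restarts; the best likelihood
    wins.

    ``session`` may be a :class:`SessionData` (optionally restricted to one
    ``context``) or a plain error array accompanied by ``reward_history``.
    """
    if isinstance(session, SessionData):
        df = session.context_subset(context) if context is not None else session.to_frame()
        e = df["e"].to_numpy(dtype=float)
        rew = df["rewarded"].to_numpy(dtype=bool)
    else:
        if reward_history is None:
            raise ValueError("reward_history required when passing a raw error series")
        e = np.asarray(session, dtype=float)
        rew = np.asarray(reward_history, dtype=bool)
    if e.size < 10:
        raise ValueError("too few trials to fit")
    x = e - e.mean()
    rng = np.random.default_rng(seed)

    theta0 = (init.as_array() if init is not None else np.array([20.0, np.std(x) * 0.7, 2.0, np.std(x) * 0.5, np.std(x) * 0.7]))
    theta0 = _clip_theta(theta0)

    n_unrew = int((~rew).sum())
    degenerate = n_unrew < 10 or n_unrew > e.size - 10
    if degenerate:
        warnings.warn(
            "all-or-nearly-all trials share one outcome; falling back to a "
            "single-step joint fit",
            stacklevel=2,
        )
        step1_theta = theta0
    else:
        # Step 1: slow kernel + baseline on the unrewarded subsequence.
        xu = e[~rew]
        xu = xu - xu.mean()
        ru = np.zeros(xu.size, dtype=bool)  # no rewarded trials in subsequence
        t1 = theta0.copy()
        t1[3] = _S_BOUNDS[0]  # sigma_RS ~ 0
        free1 = np.array([True, True, False, False, True])
        best1, best1_ll = None, -np.inf
        for k in range(max(restarts, 1)):
            ti = t1 if k == 0 else _random_theta(rng, base=t1)
            ti[3] = _S_BOUNDS[0]
            try:
                th, ll = _optimize(xu, ru, ti, free1)
            except linalg.LinAlgError:
                continue
            if ll > best1_ll:
                best1, best1_ll = th, ll
        step1_theta = best1 if best1 is not None else t1

    # Step 2: all five hyperparameters on the full series.
    free_all = np.ones(5, dtype=bool)
    init2 = step1_theta.copy()
    init2[2] = theta0[2]
    init2[3] = max(theta0[3], 0.05)
    best, best_ll = None, -np.inf
    for k in range(max(restarts, 1)):
        ti = init2 if k == 0 else _random_theta(rng, base=init2)
        try:
            th, ll = _optimize(x, rew, _clip_theta(ti), free_all)
        except linalg.LinAlgError:
            continue
        if ll > best_ll:
            best, best_ll = th, ll
    if best is None:
        raise RuntimeError("marginal-likelihood optimization failed for every restart")
    return RSGPParams.from_array(best)


def _clip_theta(theta: np.ndarray) -> np.ndarray:
    t = theta.copy()
    t[[0, 2]] = np.clip(t[[0, 2]], *_L_BOUNDS)
    t[[1, 3, 4]] = np.clip(t[[1, 3, 4]], *_S_BOUNDS)
    return t


def _random_theta(rng: np.random.Generator, base: np.ndarray) -> np.ndarray:
    jit = np.exp(rng.uniform(-1.0, 1.0, size=5))
    return _clip_theta(base * jit)


# ---------------------------------------------------------------------------
# Slow/fast decomposition
# ---------------------------------------------------------------------------

@dataclass
class SlowFastDecomposition:
    """Posterior split of an error series into slow drift and fast residual."""

    e_slow: np.ndarray
    e_fast: np.ndarray
    params: RSGPParams


def infer_e_slow(
    session: SessionData | Sequence[float],
    params: RSGPParams,
    reward_history: Sequence[bool] | None = None,
    context: Context | str | None = None,
) -> SlowFastDecomposition:
    """Posterior mean of the slow (squared-exponential) component.

    e_slow = mean(e) + sigma_SE^2 K_SE (K_RSGP)^-1 (e - mean(e)); the fast
    component is the residual e - e_slow.
    """
    if isinstance(session, SessionData):
        df = session.context_subset(context) if context is not None else session.to_frame()
        e = df["e"].to_numpy(dtype=float)
        rew = df["rewarded"].to_numpy(dtype=bool)
    else:
        if reward_history is None:
            raise ValueError("reward_history required when passing a raw error series")
        e = np.asarray(session, dtype=float)
        rew = np.asarray(reward_history, dtype=bool)
    n = e.size
    mean = e.mean()
    x = e - mean
    K = build_cov(params, rew).values
    L = _chol_jitter(K)
    alpha = linalg.cho_solve((L, True), x)
    lags = np.subtract.outer(np.arange(n), np.arange(n)).astype(float)
    Kse = params.sigma_se**2 * np.exp(-(lags**2) / (2.0 * params.l_se**2))
    e_slow = mean + Kse @ alpha
    return SlowFastDecomposition(e_slow=e_slow, e_fast=e - e_slow, params=params)
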