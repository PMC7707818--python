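"""Reinforcement-learning comparison models.

Two RL-style generative agents serve as alternatives to the reward-sensitive
GP and are rejected by the behavioral statistics:

* **MCMC sampling** — an epsilon-greedy adaptation to a continuous action
  space: keep one internal target estimate t*, propose a Gaussian perturbation
  t+, produce t_p around t+ with scalar noise, and accept/reject t+ against t*
  by a softmax (Metropolis–Hastings) rule with inverse temperature beta.
* **Directed search (DS)** — gradient following on the reward landscape:
  move the internal target along the product of the interval gradient and the
  reward gradient of the two preceding trials, plus estimation noise.  This
  scheme is brittle: once several consecutive trials go unrewarded the
  gradient signal vanishes and the agent can 'run away' from the target.

Both agents reproduce a monotonic mu(e^n) vs e^{n-1} relationship but neither
produces the U-shaped sigma(e^n) profile (no positive quadratic coefficient),
which is the discriminating signature of reward-regulated variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .task import (
    Agent,
    Context,
    Effector,
    IntervalClass,
    SessionData,
    TrialRecord,
    simulate_session,
)

__all__ = [
    "MCMCParams",
    "MCMCState",
    "MCMCAgent",
    "mcmc_accept_probability",
    "mcmc_step",
    "simulate_mcmc",
    "DSParams",
    "DSState",
    "DSAgent",
    "ds_step",
    "simulate_ds",
    "detect_runaway",
]

_ES = Context(Effector.EYE, IntervalClass.SHORT, 800.0)


# ---------------------------------------------------------------------------
# MCMC sampling model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCParams:
    """w_e and w_p are fractions of t_t (sampling and scalar production noise)."""

    w_e: float = 0.1
    w_p: float = 0.05
    beta: float = 100.0

    def __post_init__(self) -> None:
        if self.w_e <= 0 or self.w_p <= 0 or self.beta < 0:
            raise ValueError("w_e, w_p must be positive and beta non-negative")


@dataclass
class MCMCState:
    t_star: float  # incumbent internal target (ms)
    v_star: float  # reward last observed for the incumbent
    params: MCMCParams = field(default_factory=MCMCParams)

    def __post_init__(self) -> None:
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")


def mcmc_accept_probability(v_new: float, v_old: float, beta: float) -> float:
    """Softmax acceptance e^{bV+} / (e^{bV+} + e^{bV*}), overflow-guarded."""
    a, b = beta * v_new, beta * v_old
    m = max(a, b)
    ea, eb = np.exp(a - m), np.exp(b - m)
    return float(ea / (ea + eb))


def mcmc_step(
    state: MCMCState,
    reward_fn: Callable[[float], float],
    rng: np.random.Generator,
    t_t: float,
) -> tuple[MCMCState, float]:
    """One trial: propose, produce, evaluate, Metropolis-Hastings accept.

    ``reward_fn`` maps t_p (ms) to the scalar reward of this trial; the value
    assigned to the proposal is the reward of the realised t_p (value and
    execution noise are conflated by design).
    """
    p = state.params
    t_plus = state.t_star + p.w_e * t_t * rng.standard_normal()
    t_plus = max(t_plus, 1.0)
    t_p = max(t_plus + p.w_p * t_plus * rng.standard_normal(), 1.0)
    v_plus = float(reward_fn(t_p))
    if rng.random() < mcmc_accept_probability(v_plus, state.v_star, p.beta):
        new_state = MCMCState(t_star=t_plus, v_star=v_plus, params=p)
    else:
        new_state = MCMCState(t_star=state.t_star, v_star=state.v_star, params=p)
    return new_state, t_p


class MCMCAgent:
    """Task-facing wrapper around :func:`mcmc_step` for one context."""

    def __init__(self, context: Context, params: MCMCParams = MCMCParams()):
        self.context = context
        self.state = MCMCState(t_star=context.target_interval, v_star=0.0, params=params)
        self._t_plus: float | None = None

    def next_tp(self, rng: np.random.Generator) -> float:
        p = self.state.params
        t_t = self.context.target_interval
        t_plus = max(self.state.t_star + p.w_e * t_t * rng.standard_normal(), 1.0)
        t_p = max(t_plus + p.w_p * t_plus * rng.standard_normal(), 1.0)
        self._t_plus = t_plus
        self._rng = rng
        return t_p

    def observe(self, trial: TrialRecord) -> None:
        if self._t_plus is None:
            raise RuntimeError("observe() called before next_tp()")
        v_plus = trial.reward_magnitude
        if v_plus == 0.0 and trial.rewarded:
            v_plus = 1.0  # binary-feedback sessions pay no graded reward
        p_acc = mcmc_accept_probability(v_plus, self.state.v_star, self.state.params.beta)
        if self._rng.random() < p_acc:
            self.state = MCMCState(self._t_plus, v_plus, self.state.params)
        self._t_plus = None


def simulate_mcmc(
    n_trials: int,
    t_t: float = 800.0,
    w_e: float = 0.1,
    w_p: float = 0.05,
    beta: float = 100.0,
    schedule: str = "staircase",
    seed: int = 0,
    context: Context | None = None,
    **session_kwargs,
) -> SessionData:
    """Single-context session generated by the MCMC sampling agent under the
    adaptive staircase (default) or probabilistic schedule."""
    ctx = context or Context(_ES.effector, _ES.interval_class, t_t)
    params = MCMCParams(w_e=w_e, w_p=w_p, beta=beta)
    return simulate_session(
        agent_factory=lambda c: MCMCAgent(c, params),
        contexts=[ctx],
        n_trials=n_trials,
        seed=seed,
        schedule=schedule,
        **session_kwargs,
    )


# ---------------------------------------------------------------------------
# Directed search model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSParams:
    """alpha: learning rate multiplying (interval gradient ms) x (reward
    gradient ml); w_e, w_p: estimation and production noise as fractions of
    t_t.  Defaults are scaled so that a full reward swing (0.5 ml) over a
    typical interval step (~w_e * t_t) moves the internal target by ~2% of t_t.
    """

    alpha: float = 2.0
    w_e: float = 0.02
    w_p: float = 0.05

    def __post_init__(self) -> None:
        if self.w_e <= 0 or self.w_p <= 0:
            raise ValueError("w_e and w_p must be positive")


@dataclass
class DSState:
    t_prev: float
    t_prev2: float
    r_prev: float
    r_prev2: float
    params: DSParams = field(default_factory=DSParams)

    def __post_init__(self) -> None:
        if self.t_prev <= 0 or self.t_prev2 <= 0:
            raise ValueError("internal targets must be positive")


def ds_step(
    state: DSState,
    reward_fn: Callable[[float], float],
    rng: np.random.Generator,
    t_t: float,
) -> tuple[DSState, float]:
    """One trial of directed search.

    t*^n = t*^{n-1} + alpha * (t*^{n-1} - t*^{n-2}) * (r^{n-1} - r^{n-2}) + n_e,
    n_e ~ N(0, w_e * t_t); production t_p ~ N(t*^n, w_p * t_t).
    """
    p = state.params
    grad = p.alpha * (state.t_prev - state.t_prev2) * (state.r_prev - state.r_prev2)
    t_new = state.t_prev + grad + p.w_e * t_t * rng.standard_normal()
    t_new = max(t_new, 1.0)  # clamp run-away into non-physical intervals
    t_p = max(t_new + p.w_p * t_t * rng.standard_normal(), 1.0)
    r_new = float(reward_fn(t_p))
    new_state = DSState(
        t_prev=t_new, t_prev2=state.t_prev, r_prev=r_new, r_prev2=state.r_prev, params=p
    )
    return new_state, t_p


class DSAgent:
    """Task-facing directed-search agent; the first two trials produce t_p
    around t_t (initial internal targets are not otherwise constrained)."""

    def __init__(self, context: Context, params: DSParams = DSParams()):
        self.context = context
        self.params = params
        self._targets: list[float] = []
        self._rewards: list[float] = []
        self._pending_target: float | None = None

    def next_tp(self, rng: np.random.Generator) -> float:
        p = self.params
        t_t = self.context.target_interval
        if len(self._targets) < 2:
            t_new = t_t
        else:
            grad = p.alpha * (self._targets[-1] - self._targets[-2]) * (
                self._rewards[-1] - self._rewards[-2]
            )
            t_new = self._targets[-1] + grad + p.w_e * t_t * rng.standard_normal()
            t_new = max(t_new, 1.0)
        self._pending_target = t_new
        return max(t_new + p.w_p * t_t * rng.standard_normal(), 1.0)

    def observe(self, trial: TrialRecord) -> None:
        if self._pending_target is None:
            raise RuntimeError("observe() called before next_tp()")
        r = trial.reward_magnitude
        if trial.reward_magnitude == 0.0 and trial.rewarded:
            r = 1.0  # binary-feedback sessions
        self._targets.append(self._pending_target)
        self._rewards.append(r)
        self._pending_target = None


def simulate_ds(
    n_trials: int,
    t_t: float = 800.0,
    alpha: float = 2.0,
    w_e: float = 0.02,
    w_p: float = 0.05,
    schedule: str = "staircase",
    seed: int = 0,
    context: Context | None = None,
    **session_kwargs,
) -> SessionData:
    """Single-context session generated by the directed-search agent."""
    ctx = context or Context(_ES.effector, _ES.interval_class, t_t)
    params = DSParams(alpha=alpha, w_e=w_e, w_p=w_p)
    return simulate_session(
        agent_factory=lambda c: DSAgent(c, params),
        contexts=[ctx],
        n_trials=n_trials,
        seed=seed,
        schedule=schedule,
        **session_kwargs,
    )


# ---------------------------------------------------------------------------
# Run-away detection
# ---------------------------------------------------------------------------

def detect_runaway(
    session: SessionData,
    window_bound_rel: float = 0.3,
    k_unrewarded: int = 20,
) -> tuple[bool, int | None]:
    """Run-away behavior: the adaptive acceptance window has opened to at
    least ``window_bound_rel`` of t_t while more than ``k_unrewarded``
    consecutive trials went unrewarded.  Returns (flag, first offending
    1-based trial index or None)."""
    streak = 0
    for t in session.trials:
        streak = 0 if t.rewarded else streak + 1
        if streak > k_unrewarded and t.window_ms >= window_bound_rel * t.context.target_interval:
            return True, t.index
    return False, None
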