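"""Cue-Set-Go task environment.

Simulates the timing task used to probe reward-dependent regulation of motor
variability: on each trial the subject produces a target interval ``t_t``
(800 ms "Short" or 1500 ms "Long") with one of two effectors (eye saccade or
hand button press).  Reward is a truncated triangular function of the
production error, the acceptance window follows a one-up-one-down staircase
(so ~50% of trials end up rewarded), and a probabilistic-feedback variant
delivers 'correct' feedback with probability 0.7 inside a fixed window and
0.3 outside it.

The module is the package's synthetic-data generator: :func:`simulate_session`
drives any agent (constant, RSGP, MCMC, directed-search) through the task and
returns a :class:`SessionData` trial table.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Effector",
    "IntervalClass",
    "Context",
    "MONKEY_CONTEXTS",
    "TrialRecord",
    "StaircaseState",
    "SessionData",
    "Agent",
    "ConstantAgent",
    "reward_magnitude",
    "staircase_update",
    "probabilistic_feedback",
    "calibrate_window",
    "simulate_session",
    "human_target_interval",
]


class Effector(str, enum.Enum):
    EYE = "eye"
    HAND = "hand"


class IntervalClass(str, enum.Enum):
    SHORT = "short"
    LONG = "long"


@dataclass(frozen=True)
class Context:
    """One trial type: an effector paired with a target interval (ms)."""

    effector: Effector
    interval_class: IntervalClass
    target_interval: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_interval) or self.target_interval <= 0:
            raise ValueError("target_interval must be a positive finite number of ms")

    @property
    def label(self) -> str:
        return f"{self.effector.value[0].upper()}{self.interval_class.value[0].upper()}"


#: The four interleaved trial types of the monkey experiment (ES, EL, HS, HL).
MONKEY_CONTEXTS: tuple[Context, ...] = (
    Context(Effector.EYE, IntervalClass.SHORT, 800.0),
    Context(Effector.EYE, IntervalClass.LONG, 1500.0),
    Context(Effector.HAND, IntervalClass.SHORT, 800.0),
    Context(Effector.HAND, IntervalClass.LONG, 1500.0),
)


def human_target_interval(rng: np.random.Generator) -> float:
    """Session-level target for human-style sessions: N(800, 80) ms, > 0."""
    t_t = rng.normal(800.0, 80.0)
    return float(max(t_t, 1.0))


@dataclass
class TrialRecord:
    """One completed trial.

    ``e`` is the relative error (t_p - t_t) / t_t, the quantity all the
    behavioral statistics operate on.
    """

    index: int
    context: Context
    t_p: float
    e: float
    reward_magnitude: float
    rewarded: bool
    feedback: str  # 'correct' | 'incorrect' | 'none'
    time_since_prev: float
    window_ms: float  # acceptance-window half-width in force on this trial

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("trial index starts at 1")
        if self.t_p <= 0:
            raise ValueError("t_p must be positive")


@dataclass
class StaircaseState:
    """One-up-one-down staircase on the acceptance-window half-width (ms)."""

    window_halfwidth: float
    step: float
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0 or self.step <= 0 or self.floor <= 0:
            raise ValueError("staircase window, step and floor must be positive")


def staircase_update(state: StaircaseState, rewarded: bool) -> StaircaseState:
    """Shrink the window by one step after reward, grow it otherwise.

    The half-width never drops below ``state.floor`` (the task never states a
    minimum, but a non-positive window would make reward impossible forever).
    """
    delta = -state.step if rewarded else state.step
    new = max(state.window_halfwidth + delta, state.floor)
    return replace(state, window_halfwidth=new)


def reward_magnitude(e: float, window_halfwidth_rel: float, max_reward: float = 0.5) -> float:
    """Truncated triangular reward (ml) as a function of relative error.

    Maximum ``max_reward`` at e = 0, linear decrease with |e|, zero at and
    beyond the acceptance window.
    """
    if not np.isfinite(e):
        raise ValueError("relative error must be finite")
    if window_halfwidth_rel <= 0:
        raise ValueError("window half-width must be positive")
    if max_reward <= 0:
        raise ValueError("max_reward must be positive")
    frac = 1.0 - abs(e) / window_halfwidth_rel
    return max_reward * max(frac, 0.0)


def probabilistic_feedback(
    e: float,
    window_halfwidth_rel: float,
    rng: np.random.Generator,
    p_inside: float = 0.7,
    p_outside: float = 0.3,
) -> str:
    """Bernoulli 'correct'/'incorrect' feedback: P(correct)=0.7 inside the
    window, 0.3 outside (the probabilistic-reward variant)."""
    if not np.isfinite(e):
        raise ValueError("relative error must be finite")
    p = p_inside if abs(e) < window_halfwidth_rel else p_outside
    return "correct" if rng.random() < p else "incorrect"


def calibrate_window(
    e_samples: Sequence[float], target_inside_fraction: float = 0.5
) -> float:
    """Half-width containing the target fraction of |e| mass.

    Used to set the fixed window of the probabilistic-feedback task from the
    subject's overall variability so that roughly half the trials fall inside.
    """
    e = np.asarray(e_samples, dtype=float)
    if e.size < 100:
        raise ValueError("need at least 100 error samples to calibrate the window")
    if not 0.0 < target_inside_fraction <= 1.0:
        raise ValueError("target_inside_fraction must be in (0, 1]")
    abs_e = np.abs(e)
    if np.ptp(abs_e) == 0:
        raise ValueError("cannot calibrate a window from identical samples")
    return float(np.quantile(abs_e, target_inside_fraction))


class Agent(Protocol):
    """Generator-model interface: propose the next t_p, then observe the outcome.

    One agent instance serves one context; interleaved sessions hold an
    independent agent per trial type (both memory drift and the effect of
    reward are context-specific).
    """

    def next_tp(self, rng: np.random.Generator) -> float: ...

    def observe(self, trial: TrialRecord) -> None: ...


class ConstantAgent:
    """Produces t_t with optional iid Gaussian noise; a stationary reference agent."""

    def __init__(self, context: Context, noise_sd_rel: float = 0.0):
        self.context = context
        self.noise_sd_rel = noise_sd_rel

    def next_tp(self, rng: np.random.Generator) -> float:
        t_t = self.context.target_interval
        tp = t_t * (1.0 + self.noise_sd_rel * rng.standard_normal())
        return max(tp, 1.0)

    def observe(self, trial: TrialRecord) -> None:  # stateless
        pass


@dataclass
class SessionData:
    """An ordered trial table with its seed and free-form metadata."""

    trials: list[TrialRecord]
    seed: int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    # -- views -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index": t.index,
                "effector": t.context.effector.value,
                "interval_class": t.context.interval_class.value,
                "target_interval": t.context.target_interval,
                "context": t.context.label,
                "t_p": t.t_p,
                "e": t.e,
                "reward_magnitude": t.reward_magnitude,
                "rewarded": t.rewarded,
                "feedback": t.feedback,
                "time_since_prev": t.time_since_prev,
                "window_ms": t.window_ms,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def context_subset(self, context: Context | str) -> pd.DataFrame:
        """Chronological trials of one type (used for context-specific fits)."""
        label = context if isinstance(context, str) else context.label
        df = self.to_frame()
        return df[df["context"] == label].reset_index(drop=True)

    def contexts(self) -> list[Context]:
        seen: dict[str, Context] = {}
        for t in self.trials:
            seen.setdefault(t.context.label, t.context)
        return list(seen.values())

    # -- serialization -----------------------------------------------------
    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"seed": self.seed, "metadata": self.metadata}))

    @classmethod
    def read(cls, path: str | Path) -> "SessionData":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        trials = []
        for _, row in df.iterrows():
            ctx = Context(
                Effector(row["effector"]),
                IntervalClass(row["interval_class"]),
                float(row["target_interval"]),
            )
            trials.append(
                TrialRecord(
                    index=int(row["index"]),
                    context=ctx,
                    t_p=float(row["t_p"]),
                    e=float(row["e"]),
                    reward_magnitude=float(row["reward_magnitude"]),
                    rewarded=bool(row["rewarded"]),
                    feedback=str(row["feedback"]),
                    time_since_prev=float(row["time_since_prev"]),
                    window_ms=float(row["window_ms"]),
                )
            )
        return cls(trials=trials, seed=int(meta.get("seed", -1)), metadata=meta.get("metadata", {}))


def _default_step_ms(t_t: float) -> float:
    # 8 ms for the 800 ms target, 15 ms for the 1500 ms target; scale
    # proportionally (~1% of t_t) for other targets.
    if abs(t_t - 800.0) < 1e-9:
        return 8.0
    if abs(t_t - 1500.0) < 1e-9:
        return 15.0
    return 0.01 * t_t


def simulate_session(
    agent_factory: Callable[[Context], Agent],
    contexts: Sequence[Context] = MONKEY_CONTEXTS,
    n_trials: int = 2000,
    seed: int = 0,
    schedule: str = "staircase",
    initial_window_frac: float = 0.1,
    step_ms: Mapping[str, float] | None = None,
    window_floor_ms: float = 1.0,
    max_reward: float = 0.5,
    prob_window_rel: float | None = None,
    time_since_prev: float | Callable[[np.random.Generator], float] = 3.0,
    context_sequence: Sequence[int] | None = None,
    metadata: Mapping | None = None,
) -> SessionData:
    """Run a session of the Cue-Set-Go task.

    Parameters
    ----------
    agent_factory
        Called once per context to create that context's generator model.
    schedule
        ``'staircase'``: deterministic triangular reward inside an adaptive
        window (one-up-one-down). ``'probabilistic'``: binary 'correct'
        feedback at 0.7/0.3 inside/outside a fixed window (``prob_window_rel``,
        relative units; default ``initial_window_frac``).
    context_sequence
        Optional explicit sequence of indices into ``contexts``; by default
        trial types are interleaved uniformly at random.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if schedule not in ("staircase", "probabilistic"):
        raise ValueError(f"unknown schedule {schedule!r}")
    rng = np.random.default_rng(seed)
    contexts = list(contexts)
    agents = {c.label: agent_factory(c) for c in contexts}
    stairs = {
        c.label: StaircaseState(
            window_halfwidth=initial_window_frac * c.target_interval,
            step=(step_ms or {}).get(c.label, _default_step_ms(c.target_interval)),
            floor=window_floor_ms,
        )
        for c in contexts
    }
    if prob_window_rel is None:
        prob_window_rel = initial_window_frac

    trials: list[TrialRecord] = []
    for n in range(1, n_trials + 1):
        if context_sequence is not None:
            ctx = contexts[context_sequence[n - 1]]
        else:
            ctx = contexts[rng.integers(len(contexts))]
        agent = agents[ctx.label]
        t_p = agent.next_tp(rng)
        t_t = ctx.target_interval
        e = (t_p - t_t) / t_t

        if schedule == "staircase":
            st = stairs[ctx.label]
            window_ms = st.window_halfwidth
            mag = reward_magnitude(e, window_ms / t_t, max_reward)
            rewarded = mag > 0.0
            feedback = "correct" if rewarded else "incorrect"
            stairs[ctx.label] = staircase_update(st, rewarded)
        else:
            window_ms = prob_window_rel * t_t
            feedback = probabilistic_feedback(e, prob_window_rel, rng)
            rewarded = feedback == "correct"
            mag = 0.0

        dt = time_since_prev(rng) if callable(time_since_prev) else float(time_since_prev)
        trial = TrialRecord(
            index=n,
            context=ctx,
            t_p=t_p,
            e=e,
            reward_magnitude=mag,
            rewarded=rewarded,
            feedback=feedback,
            time_since_prev=0.0 if n == 1 else dt,
            window_ms=window_ms,
        )
        agent.observe(trial)
        trials.append(trial)

    return SessionData(trials=trials, seed=seed, metadata=dict(metadata or {}))
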