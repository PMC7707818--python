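"""Config-driven experiment orchestration.

An experiment is a YAML/dict config naming the stages to run in order:
``simulate`` -> ``fit`` -> ``decompose`` -> ``stats`` -> ``neural`` ->
``decode``.  Every stage writes its outputs (delimited tables / JSON) into the
experiment directory as it completes, and :func:`run_experiment` returns a
machine-readable summary dict that is also written to ``summary.json``.

Seed management: a single master seed is expanded into per-stage seeds with
``stage_seed(master, k)`` where ``k`` is the fixed ordinal of the stage in the
pipeline (simulate=0, fit=1, ...).  The expansion hashes (master, k) through
``numpy.random.SeedSequence``, so any stage can be re-run in isolation from
the config alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import alt, neural, rsgp, stats, task

__all__ = ["ExperimentConfig", "stage_seed", "run_experiment", "load_config"]

logger = logging.getLogger("rsgp_timing")

_STAGE_ORDER = ("simulate", "fit", "decompose", "stats", "neural", "decode")


def stage_seed(master: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([int(master), int(stage_index)]).generate_state(1)[0] % (2**31))


class ExperimentConfig(dict):
    """A plain dict with YAML round-trip helpers and light validation."""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        cfg = cls(yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(self), sort_keys=True))

    def validate(self) -> None:
        if "seed" not in self:
            raise ValueError("config must declare a master 'seed'")
        unknown = set(self) - {"name", "seed", "outdir", *_STAGE_ORDER}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")


def load_config(path: str | Path) -> ExperimentConfig:
    return ExperimentConfig.from_yaml(path)


_CONTEXT_BY_LABEL = {c.label: c for c in task.MONKEY_CONTEXTS}


def _make_agent_factory(spec: Mapping[str, Any]):
    kind = spec.get("agent", "rsgp")
    params = spec.get("agent_params", {}) or {}
    if kind == "rsgp":
        p = rsgp.RSGPParams(*rsgp.TABLE_GROUND_TRUTH) if not params else rsgp.RSGPParams(**params)
        return lambda c: rsgp.RSGPAgent(c, p)
    if kind == "mcmc":
        p = alt.MCMCParams(**params)
        return lambda c: alt.MCMCAgent(c, p)
    if kind == "ds":
        p = alt.DSParams(**params)
        return lambda c: alt.DSAgent(c, p)
    if kind == "const":
        return lambda c: task.ConstantAgent(c, params.get("noise_sd_rel", 0.1))
    raise ValueError(f"unknown agent kind {kind!r}")


def run_experiment(config: ExperimentConfig | Mapping[str, Any]) -> dict:
    """Execute the declared stages in order; see the module docstring.

    A stage failure raises ``RuntimeError`` naming the stage; outputs of the
    completed stages remain on disk.
    """
    cfg = ExperimentConfig(config)
    cfg.validate()
    master = int(cfg["seed"])
    outdir = Path(cfg.get("outdir", "experiment_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"name": cfg.get("name", "experiment"), "seed": master}

    session: task.SessionData | None = None
    fitted: dict[str, rsgp.RSGPParams] = {}
    decomposed: dict[str, rsgp.SlowFastDecomposition] = {}

    for k, stage in enumerate(_STAGE_ORDER):
        if stage not in cfg or cfg[stage] in (None, False):
            continue
        spec = cfg[stage] if isinstance(cfg[stage], Mapping) else {}
        seed = stage_seed(master, k)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            if stage == "simulate":
                labels = spec.get("contexts", ["ES"])
                contexts = [_CONTEXT_BY_LABEL[l] for l in labels]
                session = task.simulate_session(
                    agent_factory=_make_agent_factory(spec),
                    contexts=contexts,
                    n_trials=int(spec.get("n_trials", 2000)),
                    seed=seed,
                    schedule=spec.get("schedule", "staircase"),
                    initial_window_frac=float(spec.get("initial_window_frac", 0.1)),
                )
                session.write(outdir / "session.tsv")
                frac = float(np.mean([t.rewarded for t in session.trials]))
                summary["simulate"] = {
                    "n_trials": len(session),
                    "reward_fraction": frac,
                    "agent": spec.get("agent", "rsgp"),
                }

            elif stage == "fit":
                session = _require(session, cfg, outdir, "fit")
                out = {}
                for label in spec.get("contexts", [c.label for c in session.contexts()]):
                    p = rsgp.fit_mml(
                        session,
                        context=label,
                        restarts=int(spec.get("restarts", 3)),
                        seed=seed,
                    )
                    fitted[label] = p
                    out[label] = dict(zip(("l_se", "sigma_se", "l_rs", "sigma_rs", "sigma_0"), p.as_array().tolist()))
                (outdir / "rsgp_params.json").write_text(json.dumps(out, indent=2))
                summary["fit"] = out

            elif stage == "decompose":
                session = _require(session, cfg, outdir, "decompose")
                rows = []
                for label, p in fitted.items():
                    dec = rsgp.infer_e_slow(session, p, context=label)
                    decomposed[label] = dec
                    df = session.context_subset(label)
                    for i in range(len(df)):
                        rows.append(
                            {
                                "context": label,
                                "within_index": i,
                                "e": df["e"].iat[i],
                                "e_slow": dec.e_slow[i],
                                "e_fast": dec.e_fast[i],
                            }
                        )
                import pandas as pd

                pd.DataFrame(rows).to_csv(outdir / "decomposition.tsv", sep="\t", index=False)
                summary["decompose"] = {l: float(np.std(d.e_slow)) for l, d in decomposed.items()}

            elif stage == "stats":
                session = _require(session, cfg, outdir, "stats")
                pairing = spec.get("pairing", "same_type")
                pairs = stats.pair_trials(session, pairing=pairing)
                es = stats.error_stats_by_prev(
                    pairs, n_bins=int(spec.get("n_bins", 10)), pairing=pairing
                )
                summary["stats"] = {
                    "pairing": pairing,
                    "n_pairs": es.n_pairs,
                    "m0": es.m0,
                    "m1": es.m1,
                    "m1_ci": list(es.m1_ci),
                    "s0": es.s0,
                    "s1": es.s1,
                    "s2": es.s2,
                    "s2_ci": list(es.s2_ci),
                }
                (outdir / "error_stats.json").write_text(json.dumps(summary["stats"], indent=2))

            elif stage == "neural":
                session = _require(session, cfg, outdir, "neural")
                label = spec.get("context") or session.contexts()[0].label
                if label not in decomposed:
                    p = fitted.get(label) or rsgp.RSGPParams(*rsgp.TABLE_GROUND_TRUTH)
                    decomposed[label] = rsgp.infer_e_slow(session, p, context=label)
                df = session.context_subset(label)
                spikes = neural.synth_spike_counts(
                    decomposed[label].e_slow,
                    df["rewarded"].to_numpy(dtype=bool),
                    n_neurons=int(spec.get("n_neurons", 17)),
                    variance_coupling=spec.get("profile", "thalamus_like"),
                    rng=np.random.default_rng(seed),
                )
                np.savetxt(outdir / "spike_counts.tsv", spikes.counts, fmt="%d", delimiter="\t")
                summary["neural"] = {
                    "context": label,
                    "n_neurons": spikes.n_neurons,
                    "mean_count": float(spikes.counts.mean()),
                    "profile": spec.get("profile", "thalamus_like"),
                }
                cfg["_spikes"] = spikes  # in-memory handoff
                cfg["_neural_context"] = label

            elif stage == "decode":
                spikes = cfg.get("_spikes")
                if spikes is None:
                    raise ValueError("decode stage requires the neural stage")
                label = cfg["_neural_context"]
                target_kind = spec.get("target", "eslow")
                df = session.context_subset(label)
                target = (
                    decomposed[label].e_slow
                    if target_kind == "eslow"
                    else df["t_p"].to_numpy(dtype=float)
                )
                fit = neural.fit_drift_direction(spikes, target, split_seed=seed)
                summary["decode"] = {
                    "target": target_kind,
                    "r_heldout": fit.r_heldout,
                    "null_q01": fit.null_quantiles[0],
                    "null_q99": fit.null_quantiles[1],
                    "significant": bool(fit.significant),
                }
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            _write_summary(outdir, summary)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    cfg.pop("_spikes", None)
    cfg.pop("_neural_context", None)
    _write_summary(outdir, summary)
    return summary


def _require(session, cfg, outdir, stage):
    if session is not None:
        return session
    path = Path(cfg.get("outdir", "experiment_out")) / "session.tsv"
    if path.exists():
        return task.SessionData.read(path)
    raise ValueError(f"stage {stage!r} needs a session (run or point to 'simulate' first)")


def _write_summary(outdir: Path, summary: dict) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
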