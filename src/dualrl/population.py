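"""Population simulation, behavioural metrics and tabular outputs.

Runs independent agents over a scheduled experiment, collects per-trial logs
(peck target, reward, tagged prediction errors) into tidy DataFrames, and
computes the aggregates the behavioural literature reports: cumulative peck
curves per key with mean ± SEM across the population, the worst-case
reference (a peck on every trial), percentages of available rewards
retrieved, and per-session prediction-error traces at CS appearance, reward
delivery and omission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .agent import Agent, AgentParams
from .mdp import Feature
from .tasks import ExperimentSpec, Schedule

__all__ = [
    "PopulationResult",
    "run_population",
    "rewards_retrieved_pct",
    "rpe_summary",
    "cumulative_curves",
    "write_outputs",
]

_TRIAL_COLUMNS = [
    "agent", "seed", "trial", "session", "label",
    "pecked_key", "rewarded", "n_actions", "actions",
]
_RPE_COLUMNS = ["agent", "trial", "session", "event", "delta"]


@dataclass
class PopulationResult:
    """Trial-level and RPE-level logs for a simulated population."""

    trials: pd.DataFrame
    rpes: pd.DataFrame
    spec: ExperimentSpec
    params: AgentParams
    base_seed: int
    seeds: Tuple[int, ...]

    @property
    def n_agents(self) -> int:
        return len(self.seeds)

    def concat(self, other: "PopulationResult") -> "PopulationResult":
        """Pool two populations (e.g. STs and GTs) for joint summaries.

        Agent indices of ``other`` are shifted past ours; the pooled result
        keeps this population's spec and params for bookkeeping.
        """
        shift = self.n_agents
        ot = other.trials.copy()
        ot["agent"] += shift
        orp = other.rpes.copy()
        orp["agent"] += shift
        return PopulationResult(
            trials=pd.concat([self.trials, ot], ignore_index=True),
            rpes=pd.concat([self.rpes, orp], ignore_index=True),
            spec=self.spec,
            params=self.params,
            base_seed=self.base_seed,
            seeds=self.seeds + other.seeds,
        )


def run_population(
    spec: ExperimentSpec,
    params: AgentParams,
    n_agents: Optional[int] = None,
    base_seed: int = 0,
) -> PopulationResult:
    """Simulate ``n_agents`` independent agents through a scheduled experiment.

    Each agent runs on its own freshly built task (phase changes are applied
    per agent) with seed ``base_seed + i``.  Identical inputs give
    bit-identical results.
    """
    n_agents = spec.n_agents if n_agents is None else int(n_agents)
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    seeds = tuple(base_seed + i for i in range(n_agents))
    trial_rows = []
    rpe_rows = []
    for i, seed in enumerate(seeds):
        task, schedule = spec.build()
        agent = Agent(task, params, seed=seed)
        label = ""
        for t in range(spec.n_trials):
            change = schedule.maybe_apply(task, t)
            if change is not None:
                label = change.label
            log = agent.run_trial(t)
            session = t // spec.trials_per_session
            trial_rows.append(
                (
                    i, seed, t, session, label,
                    log.pecked_key or "none",
                    log.rewarded,
                    len(log.actions),
                    ";".join(log.actions),
                )
            )
            for rec in log.rpes:
                rpe_rows.append((i, t, session, rec.event, rec.delta))
    trials = pd.DataFrame(trial_rows, columns=_TRIAL_COLUMNS)
    rpes = pd.DataFrame(rpe_rows, columns=_RPE_COLUMNS)
    return PopulationResult(trials, rpes, spec, params, base_seed, seeds)


def rewards_retrieved_pct(
    result: PopulationResult, window: Tuple[int, int]
) -> float:
    """Percent of available rewards retrieved over ``window``.

    ``window`` is a half-open trial range ``(start, stop)`` in 0-based trial
    indices; one reward is available per trial, so the percentage is 100 ×
    rewarded trials / trials, pooled over agents.
    """
    start, stop = window
    if stop <= start:
        raise ValueError("window must be a non-empty (start, stop) trial range")
    n_trials = result.spec.n_trials
    if start < 0 or stop > n_trials:
        raise ValueError(f"window {window} outside the {n_trials}-trial run")
    sel = result.trials[(result.trials.trial >= start) & (result.trials.trial < stop)]
    return 100.0 * float(sel.rewarded.mean())


def rpe_summary(result: PopulationResult) -> pd.DataFrame:
    """Per-session mean ± SEM of δ at CS appearance, US and omission.

    Sessions with no occurrence of an event contribute no row for it.  Pool
    sign- and goal-trackers with :meth:`PopulationResult.concat` first to get
    whole-population traces.
    """
    if result.rpes.empty:
        return pd.DataFrame(columns=["session", "event", "mean", "sem", "n"])
    g = result.rpes.groupby(["session", "event"])["delta"]
    out = g.agg(mean="mean", sem="sem", n="size").reset_index()
    return out.sort_values(["session", "event"], ignore_index=True)


def cumulative_curves(result: PopulationResult) -> pd.DataFrame:
    """Cumulative peck and reward curves, per trial, with mean ± SEM.

    One row per trial with, for each key k present in the task, per-population
    ``pecks_k_mean``/``pecks_k_sem`` of the cumulative pecks on k, plus the
    cumulative rewards and the worst-case reference (a peck at every trial,
    i.e. the trial counter).
    """
    trials = result.trials
    n_trials = result.spec.n_trials
    idx = np.arange(n_trials)
    out = pd.DataFrame({"trial": idx})
    agents = sorted(trials.agent.unique())

    def agg(per_agent: np.ndarray, name: str) -> None:
        out[f"{name}_mean"] = per_agent.mean(axis=0)
        if per_agent.shape[0] > 1:
            sem = per_agent.std(axis=0, ddof=1) / np.sqrt(per_agent.shape[0])
        else:
            sem = np.zeros(n_trials)
        out[f"{name}_sem"] = sem

    for key in ("K", "I", "C"):
        if (trials.pecked_key == key).any() or key in {
            k.value for k in result.spec.build()[0].keys
        }:
            mat = np.vstack(
                [
                    np.cumsum(
                        (trials[trials.agent == a].sort_values("trial").pecked_key == key).to_numpy()
                    )
                    for a in agents
                ]
            )
            agg(mat, f"pecks_{key}")
    rew = np.vstack(
        [
            np.cumsum(trials[trials.agent == a].sort_values("trial").rewarded.to_numpy())
            for a in agents
        ]
    )
    agg(rew, "rewards")
    out["worst_case"] = idx + 1
    return out


def write_outputs(
    result: PopulationResult,
    out_dir: Union[str, Path],
    plot: bool = False,
) -> dict:
    """Write trial logs, aggregate curves, RPE traces and a run manifest.

    Emits ``trials.csv``, ``curves.csv``, ``rpe.csv`` and ``manifest.json``
    under ``out_dir`` (created if missing); with ``plot=True`` also renders
    ``curves.png``.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(out / "trials.csv", index=False)
    curves = cumulative_curves(result)
    curves.to_csv(out / "curves.csv", index=False)
    rpe_summary(result).to_csv(out / "rpe.csv", index=False)
    manifest = {
        "version": __version__,
        "experiment": result.spec.experiment,
        "protocol": result.spec.protocol,
        "n_trials": result.spec.n_trials,
        "trials_per_session": result.spec.trials_per_session,
        "reversals": list(result.spec.reversals),
        "phase_lengths": list(result.spec.phase_lengths),
        "reward_magnitude": result.spec.reward_magnitude,
        "params": {
            "omega": result.params.omega,
            "alpha": result.params.alpha,
            "tau": result.params.tau,
            "gamma": result.params.gamma,
            "u_mag": result.params.u_mag,
            "u_cont": result.params.u_cont,
            "v0_key": result.params.v0_key,
            "v0_mag": result.params.v0_mag,
            "v0_food": result.params.v0_food,
            "profile": result.params.profile,
        },
        "n_agents": result.n_agents,
        "base_seed": result.base_seed,
        "seeds": list(result.seeds),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if plot:
        _plot_curves(curves, result, out / "curves.png")
    return manifest


def _plot_curves(curves: pd.DataFrame, result: PopulationResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {"K": ("tab:red", "negative key"),
              "I": ("tab:green", "irrelevant key"),
              "C": ("tab:purple", "continuous key")}
    for key, (color, label) in styles.items():
        col = f"pecks_{key}_mean"
        if col in curves:
            ax.plot(curves.trial, curves[col], color=color, label=label)
            ax.fill_between(
                curves.trial,
                curves[col] - curves[f"pecks_{key}_sem"],
                curves[col] + curves[f"pecks_{key}_sem"],
                color=color,
                alpha=0.2,
            )
    ax.plot(curves.trial, curves.worst_case, ":", color="grey", label="worst case")
    ax.set_xlabel("trial")
    ax.set_ylabel("cumulative pecks")
    ax.set_title(
        f"{result.spec.experiment} — {result.params.profile or 'custom'} profile"
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
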