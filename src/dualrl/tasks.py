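"""Builders for the simulated negative-automaintenance experiments.

Three task layouts are provided:

* **Experiment 1** — the classic omission schedule.  A single key light (K)
  announces food; pecking it cancels the delivery and ends the trial.
* **Experiment 3** — Experiment 1 plus an *irrelevant* key (I) that lights up
  with K but whose pecks have no effect.  The roles of the two keys can be
  reversed, silently, at scheduled trials.
* **Experiment 4** — Experiment 3 plus a *continuous* key (C) that stays lit
  through trials and the inter-trial interval; pecks on it are harmless.
  Four three-phase protocols activate different key subsets:

  ========  =========  =========  =======
  protocol  phase 1    phase 2    phase 3
  ========  =========  =========  =======
  A         K          K + C      C
  B         K          K + C + I  C
  C         K + C      K + C      C
  D         K + C + I  K + C + I  C
  ========  =========  =========  =======

Phase and block switches never touch an agent's learned model or values —
only the task's routing changes, as in the animal experiments where the
contingencies were swapped without informing the bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .mdp import (
    Action,
    ActionKind,
    ConfigurationError,
    Feature,
    State,
    TaskMDP,
    Transition,
)

__all__ = [
    "PROTOCOLS",
    "Schedule",
    "PhaseChange",
    "ExperimentSpec",
    "build_experiment1",
    "build_experiment3",
    "build_experiment4",
    "load_experiment",
    "EXPERIMENT_NAMES",
]

#: Key sets per phase for the four Experiment-4 protocols.
PROTOCOLS: Dict[str, Tuple[frozenset, ...]] = {
    "A": (frozenset("K"), frozenset("KC"), frozenset("C")),
    "B": (frozenset("K"), frozenset("KCI"), frozenset("C")),
    "C": (frozenset("KC"), frozenset("KC"), frozenset("C")),
    "D": (frozenset("KCI"), frozenset("KCI"), frozenset("C")),
}

EXPERIMENT_NAMES = ("exp1", "exp3", "exp4-A", "exp4-B", "exp4-C", "exp4-D")

_CLOSE = {Feature.K: "s2", Feature.I: "s2I", Feature.C: "s2C"}
_POST = {Feature.K: "s5", Feature.I: "s5I", Feature.C: "s5C"}


def _build_task(
    name: str,
    keys: Sequence[Feature],
    negative: Optional[Feature],
    reward_magnitude: float = 1.0,
) -> TaskMDP:
    """Assemble the shared task skeleton with one path per key light.

    Core layout (Experiment 1 with ``keys = (K,)``): the trial starts in an
    empty state s0; exploring turns the key light on (s1); the agent may
    approach a key (close-state, then engage or refrain), approach the
    magazine (s4), or keep exploring (s3, s6).  Food appears after the key
    phase resolves; the only rewarded action is ``eat`` in s7, and every
    route returns to s0, which ends the trial.
    """
    keys = [Feature(k) for k in keys]
    lit = frozenset(k for k in keys if k is not Feature.C)
    m = frozenset({Feature.M})
    fm = frozenset({Feature.F, Feature.M})

    states = [
        State("s0", m, initial=True, terminal=True),
        State("s1", lit | m),
        State("s3", lit | m),
        State("s4", lit | m),
        State("s6", fm),
        State("s7", fm),
    ]
    actions: Dict[str, List[Action]] = {
        "s0": [Action("exp", ActionKind.EXP, Feature.NULL)],
        "s1": [Action("goM", ActionKind.GO, Feature.M),
               Action("exp", ActionKind.EXP, Feature.NULL)],
        "s3": [Action("exp", ActionKind.EXP, Feature.NULL)],
        "s4": [Action("eng", ActionKind.ENG, Feature.M),
               Action("ngo", ActionKind.NGO, Feature.M)],
        "s6": [Action("goM", ActionKind.GO, Feature.M)],
        "s7": [Action("eat", ActionKind.EAT, Feature.F)],
    }
    transitions: Dict[tuple, Transition] = {
        ("s0", "exp"): Transition("s1", event="CS"),
        ("s1", "goM"): Transition("s4"),
        ("s1", "exp"): Transition("s3"),
        ("s3", "exp"): Transition("s6"),
        ("s4", "eng"): Transition("s7"),
        ("s4", "ngo"): Transition("s7"),
        ("s6", "goM"): Transition("s7"),
        ("s7", "eat"): Transition("s0", event="US", rewarded=True),
    }
    key_paths: Dict[Feature, Dict[str, str]] = {}
    for k in keys:
        close, post = _CLOSE[k], _POST[k]
        states.append(State(close, lit | m))
        states.append(State(post, fm))
        actions["s1"].insert(
            len(key_paths), Action(f"go{k.value}", ActionKind.GO, k, path=k)
        )
        actions[close] = [
            Action("eng", ActionKind.ENG, k, path=k),
            Action("ngo", ActionKind.NGO, k, path=k),
        ]
        actions[post] = [Action("goM", ActionKind.GO, Feature.M, path=k)]
        transitions[("s1", f"go{k.value}")] = Transition(close)
        # (close, "eng") is routed by set_phase: omission if k is negative
        transitions[(close, "ngo")] = Transition(post)
        transitions[(post, "goM")] = Transition("s7")
        key_paths[k] = {"close": close, "post": post}

    return TaskMDP(
        name,
        states,
        actions,
        transitions,
        key_paths,
        reward_magnitude=reward_magnitude,
        active=keys,
        negative=negative,
    )


# -- schedules -----------------------------------------------------------


@dataclass(frozen=True)
class PhaseChange:
    """Scheduled rerouting applied just before ``trial`` is run."""

    trial: int
    active: frozenset
    negative: Optional[Feature]
    label: str

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "active": sorted(k.value for k in self.active),
            "negative": self.negative.value if self.negative else None,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseChange":
        return cls(
            trial=int(d["trial"]),
            active=frozenset(Feature(k) for k in d["active"]),
            negative=Feature(d["negative"]) if d.get("negative") else None,
            label=d.get("label", ""),
        )


class Schedule:
    """An ordered list of phase changes, applied by trial index."""

    def __init__(self, changes: Sequence[PhaseChange]) -> None:
        self.changes = tuple(sorted(changes, key=lambda c: c.trial))
        trials = [c.trial for c in self.changes]
        if len(set(trials)) != len(trials):
            raise ConfigurationError("duplicate trials in schedule")
        self._by_trial = {c.trial: c for c in self.changes}

    def maybe_apply(self, task: TaskMDP, trial: int) -> Optional[PhaseChange]:
        """Apply the change scheduled at ``trial``, if any, and return it."""
        change = self._by_trial.get(trial)
        if change is not None:
            task.set_phase(change.active, change.negative)
        return change

    def label_at(self, trial: int) -> str:
        label = ""
        for c in self.changes:
            if c.trial <= trial:
                label = c.label
        return label

    def to_dicts(self) -> List[dict]:
        return [c.to_dict() for c in self.changes]


# -- experiment builders -------------------------------------------------


def build_experiment1(reward_magnitude: float = 1.0) -> Tuple[TaskMDP, Schedule]:
    """Single negative key; 8 states; omission contingency on K throughout."""
    task = _build_task("exp1", (Feature.K,), Feature.K, reward_magnitude)
    sched = Schedule([PhaseChange(0, frozenset({Feature.K}), Feature.K, "A")])
    return task, sched


def build_experiment3(
    reversals: Sequence[int] = (200, 400, 600),
    reward_magnitude: float = 1.0,
) -> Tuple[TaskMDP, Schedule]:
    """Negative + irrelevant key, with silent role reversals.

    The task starts in block A (K negative, I irrelevant); at each trial
    index in ``reversals`` the omission contingency swaps keys.
    """
    reversals = [int(t) for t in reversals]
    if any(b <= a for a, b in zip(reversals, reversals[1:])) or any(
        t <= 0 for t in reversals
    ):
        raise ConfigurationError("reversal trials must be strictly increasing and > 0")
    task = _build_task("exp3", (Feature.K, Feature.I), Feature.K, reward_magnitude)
    both = frozenset({Feature.K, Feature.I})
    changes = [PhaseChange(0, both, Feature.K, "A")]
    for i, t in enumerate(reversals):
        neg = Feature.I if i % 2 == 0 else Feature.K
        changes.append(PhaseChange(t, both, neg, "B" if i % 2 == 0 else "A"))
    return task, Schedule(changes)


def build_experiment4(
    protocol: str,
    phase_lengths: Sequence[int] = (300, 300, 300),
    reward_magnitude: float = 1.0,
) -> Tuple[TaskMDP, Schedule]:
    """Three-phase protocol with the continuous key; K is negative when lit."""
    protocol = protocol.upper()
    if protocol not in PROTOCOLS:
        raise ConfigurationError(f"unknown protocol {protocol!r} (expected A-D)")
    if len(phase_lengths) != 3 or any(n <= 0 for n in phase_lengths):
        raise ConfigurationError("phase_lengths must be three positive trial counts")
    phases = PROTOCOLS[protocol]
    task = _build_task(
        f"exp4-{protocol}",
        (Feature.K, Feature.I, Feature.C),
        Feature.K if Feature.K in phases[0] else None,
        reward_magnitude,
    )
    starts = [0, phase_lengths[0], phase_lengths[0] + phase_lengths[1]]
    changes = [
        PhaseChange(
            start,
            frozenset(Feature(k) for k in keys),
            Feature.K if "K" in keys else None,
            f"phase{i + 1}",
        )
        for i, (start, keys) in enumerate(zip(starts, phases))
    ]
    task.set_phase(changes[0].active, changes[0].negative)
    return task, Schedule(changes)


# -- experiment specs and bundled fixtures --------------------------------


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully described simulated experiment: task layout + run defaults."""

    experiment: str  #: "exp1", "exp3" or "exp4"
    n_trials: int = 500
    trials_per_session: int = 50
    n_agents: int = 8
    reversals: Tuple[int, ...] = ()
    protocol: Optional[str] = None
    phase_lengths: Tuple[int, int, int] = (300, 300, 300)
    reward_magnitude: float = 1.0

    def build(self) -> Tuple[TaskMDP, Schedule]:
        if self.experiment == "exp1":
            return build_experiment1(self.reward_magnitude)
        if self.experiment == "exp3":
            return build_experiment3(self.reversals, self.reward_magnitude)
        if self.experiment == "exp4":
            if self.protocol is None:
                raise ConfigurationError("exp4 requires a protocol (A-D)")
            return build_experiment4(
                self.protocol, self.phase_lengths, self.reward_magnitude
            )
        raise ConfigurationError(f"unknown experiment {self.experiment!r}")

    @classmethod
    def default(cls, name: str, **overrides) -> "ExperimentSpec":
        """Spec with the package's default run lengths for a named experiment."""
        base = name.lower()
        if base == "exp1":
            spec = cls("exp1", n_trials=500, n_agents=8)
        elif base == "exp3":
            spec = cls("exp3", n_trials=800, n_agents=8, reversals=(200, 400, 600))
        elif base.startswith("exp4"):
            proto = base.split("-", 1)[1].upper() if "-" in base else "A"
            spec = cls("exp4", n_trials=900, n_agents=2, protocol=proto)
        else:
            raise ConfigurationError(f"unknown experiment {name!r}")
        if overrides:
            from dataclasses import replace

            spec = replace(spec, **overrides)
        return spec

    def to_dict(self) -> dict:
        task, sched = self.build()
        return {
            "experiment": self.experiment,
            "n_trials": self.n_trials,
            "trials_per_session": self.trials_per_session,
            "n_agents": self.n_agents,
            "reversals": list(self.reversals),
            "protocol": self.protocol,
            "phase_lengths": list(self.phase_lengths),
            "reward_magnitude": self.reward_magnitude,
            "schedule": sched.to_dicts(),
            "task": task.to_dict(),
        }


def load_experiment(name: str) -> Tuple[TaskMDP, Schedule, ExperimentSpec]:
    """Load a bundled experiment fixture (exp1, exp3, exp4-A…exp4-D).

    The task and schedule are reconstructed from the serialized tables in the
    fixture file, not from the builders, so the file is an independent
    description of the task.
    """
    if name not in EXPERIMENT_NAMES:
        raise ConfigurationError(
            f"unknown experiment {name!r} (expected one of {EXPERIMENT_NAMES})"
        )
    text = resources.files("dualrl.data").joinpath(f"{name}.yaml").read_text()
    data = yaml.safe_load(text)
    task = TaskMDP.from_dict(data["task"])
    sched = Schedule([PhaseChange.from_dict(d) for d in data["schedule"]])
    spec = ExperimentSpec(
        experiment=data["experiment"],
        n_trials=data["n_trials"],
        trials_per_session=data["trials_per_session"],
        n_agents=data["n_agents"],
        reversals=tuple(data["reversals"]),
        protocol=data["protocol"],
        phase_lengths=tuple(data["phase_lengths"]),
        reward_magnitude=data["reward_magnitude"],
    )
    sched.maybe_apply(task, 0)
    return task, sched, spec
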