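"""The full agent: ω-weighted integration of both systems and the trial loop.

Action values are a weighted sum of the model-based advantage and the
feature value of the action's focus,

    P(s,a) = (1−ω)·A(s,a) + ω·V(f(s,a)),       a ≠ ngo
    P(s,a) = (1−ω)·A(s,a),                     a = ngo

— refraining from engaging a stimulus does not benefit from the motivational
bonus of that stimulus.  A softmax with temperature τ converts the values of
the currently available actions into choice probabilities.  High-ω agents
behave as sign-trackers (drawn to reward-predicting key lights), low-ω agents
as goal-trackers (magazine-oriented reward maximisers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import fmf, mb
from .mdp import ActionKind, ConfigurationError, Feature, KEY_FEATURES, TaskMDP

__all__ = [
    "AgentParams",
    "ST_PRESET",
    "GT_PRESET",
    "TrialLog",
    "Agent",
    "integrated_value",
    "softmax_probabilities",
    "select_action",
]

#: Events that give rise to a logged prediction-error record.
TAGGED_EVENTS = ("CS", "US", "omission")


@dataclass(frozen=True)
class AgentParams:
    """The eight model parameters, with sign-tracker / goal-tracker presets.

    ``v0_key``, ``v0_mag`` and ``v0_food`` initialise the feature values of
    the conditioned key, magazine and food, standing in for pre-training
    (magazine familiarisation, brief autoshaping); they wash out with
    learning.
    """

    omega: float = 0.5  #: weight of the feature-based system in the mix
    alpha: float = 0.15  #: learning rate of the feature values
    tau: float = 0.2  #: softmax temperature (divisor)
    gamma: float = 0.9  #: discount rate, shared by both systems
    u_mag: float = 0.3  #: ITI degradation of the magazine value
    u_cont: float = 0.2  #: ITI degradation of the continuous-key value
    v0_key: float = 0.0
    v0_mag: float = 0.2
    v0_food: float = 0.2
    profile: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.omega <= 1:
            raise ConfigurationError("omega must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if not 0 <= self.gamma < 1:
            raise ConfigurationError("gamma must lie in [0, 1)")
        for u in (self.u_mag, self.u_cont):
            if not 0 <= u <= 1:
                raise ConfigurationError("ITI decay factors must lie in [0, 1]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "AgentParams":
        """Named parameter profile: ``"st"`` (sign-tracker) or ``"gt"``."""
        base = {"st": ST_PRESET, "gt": GT_PRESET}.get(name.lower())
        if base is None:
            raise ConfigurationError(f"unknown profile {name!r} (expected 'st' or 'gt')")
        return replace(base, **overrides) if overrides else base


ST_PRESET = AgentParams(
    omega=0.9, v0_key=0.0, v0_mag=0.2, v0_food=0.2, profile="ST"
)
GT_PRESET = AgentParams(
    omega=0.2, v0_key=0.8, v0_mag=0.2, v0_food=0.2, profile="GT"
)


def integrated_value(
    adv: float, values: fmf.FeatureValues, action, omega: float
) -> float:
    """Weighted sum of advantage and feature value; no bonus for ngo."""
    if action.kind is ActionKind.NGO:
        return (1.0 - omega) * adv
    return (1.0 - omega) * adv + omega * values[action.focus]


def softmax_probabilities(values: Sequence[float], tau: float) -> np.ndarray:
    """Boltzmann distribution exp(v/τ)/Σexp, stabilised by a max shift."""
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("at least one action value is required")
    z = np.exp((v - v.max()) / tau)
    return z / z.sum()


def select_action(values: Sequence[float], tau: float, rng: np.random.Generator) -> int:
    """Sample an action index from the softmax over ``values``."""
    p = softmax_probabilities(values, tau)
    return int(rng.choice(len(p), p=p))


@dataclass
class TrialLog:
    """Per-trial record: the action path, peck target, reward and tagged δs."""

    trial: int
    actions: Tuple[str, ...]
    pecked_key: Optional[str]  #: "K", "I", "C" or None
    rewarded: bool
    rpes: Tuple[fmf.RPERecord, ...]
    session: int = 0
    label: str = ""


class Agent:
    """A single simulated animal: both learning systems plus a choice rule.

    Identical ``(task, params, seed)`` triples produce bit-identical trial
    logs; populations draw per-member seeds from a counter-based (Philox)
    stream keyed ``base_seed + i``.

    ``init_system`` decides where the pre-training triple lands: ``"fmf"``
    (default) seeds the feature values of key/magazine/food; ``"mb"`` seeds
    the Q-table entries of actions focused on those features instead.
    """

    def __init__(
        self,
        task: TaskMDP,
        params: AgentParams,
        seed: int = 0,
        init_system: str = "fmf",
    ) -> None:
        self.task = task
        self.params = params
        self.seed = int(seed)
        self.rng = np.random.Generator(np.random.Philox(self.seed))
        self.model = mb.WorldModel()
        self.q: Dict[Tuple[str, str], float] = {}
        init = {
            Feature.K: params.v0_key,
            Feature.M: params.v0_mag,
            Feature.F: params.v0_food,
        }
        if init_system == "fmf":
            self.values = fmf.FeatureValues(params.alpha, init=init)
        elif init_system == "mb":
            self.values = fmf.FeatureValues(params.alpha)
            for sid in task.states:
                for a in task._actions.get(sid, ()):
                    if a.focus in init:
                        self.q[(sid, a.name)] = init[a.focus]
        else:
            raise ConfigurationError("init_system must be 'fmf' or 'mb'")

    # -- choice ----------------------------------------------------------

    def action_values(self, state) -> Tuple[list, np.ndarray]:
        """Available actions in ``state`` and their integrated values."""
        acts = self.task.available_actions(state)
        adv = mb.advantage(self.q, state.id if hasattr(state, "id") else state, acts)
        vals = np.array(
            [
                integrated_value(adv[a.name], self.values, a, self.params.omega)
                for a in acts
            ]
        )
        return acts, vals

    # -- learning --------------------------------------------------------

    def run_trial(
        self,
        trial: int = 0,
        policy: Optional[Callable] = None,
    ) -> TrialLog:
        """Run one episode: select → step → update model/Q → RPE → update V.

        ``policy(state, actions) -> Action`` overrides the softmax choice
        (used for forced-policy probes); learning proceeds identically.
        The ITI value degradation is applied once, after the trial ends.
        """
        task, p = self.task, self.params
        state = task.initial_state
        taken: List[str] = []
        rpes: List[fmf.RPERecord] = []
        pecked: Optional[str] = None
        rewarded = False
        while True:
            acts, vals = self.action_values(state)
            if policy is None:
                a = acts[select_action(vals, p.tau, self.rng)]
            else:
                a = policy(state, acts)
            res = task.step(state, a)
            # world model first, replanning only when the model moved
            if self.model.update(state.id, a.name, res.state.id, res.reward, res.ends_trial):
                self.q = mb.solve_q(self.model, p.gamma, q0=self.q)
            # prediction error on pre-update values
            nxt = None if res.ends_trial else task.feature_set(res.state)
            delta = fmf.rpe(self.values, a.focus, nxt, res.reward, p.gamma)
            if res.event in TAGGED_EVENTS:
                rpes.append(fmf.RPERecord(trial, res.event, delta))
            if a.focus is not Feature.NULL:
                self.values.update(a.focus, delta)
            if a.kind is ActionKind.ENG and a.focus in KEY_FEATURES:
                pecked = a.focus.value
            if res.reward > 0:
                rewarded = True
            taken.append(f"{state.id}:{a.name}")
            if res.ends_trial:
                break
            state = res.state
        present = {Feature.M} | (
            {Feature.C} if Feature.C in task.active_keys else set()
        )
        fmf.iti_decay(self.values, present, p.u_mag, p.u_cont)
        return TrialLog(
            trial=trial,
            actions=tuple(taken),
            pecked_key=pecked,
            rewarded=rewarded,
            rpes=tuple(rpes),
        )
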