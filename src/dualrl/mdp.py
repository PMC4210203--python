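"""Finite-horizon factored MDP core for discrete conditioning tasks.

Each trial of a conditioning experiment is modelled as a single episode in a
small deterministic MDP.  States are described by the set of salient stimuli
(*features*) they contain — e.g. a lit key light, the food magazine, delivered
food — and every action is directed at a single feature (engage a key, go to
the magazine, eat) or at nothing in particular (explore).  Key-light *paths*
through the MDP can be switched on and off between phases of an experiment,
and the omission contingency (which key cancels the reward when pecked) can be
re-routed without the agent being told.

The start state doubles as the episode terminal: any transition back into it
ends the trial, and the next trial begins from it afresh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "ConfigurationError",
    "UnknownStateError",
    "Feature",
    "KEY_FEATURES",
    "ActionKind",
    "Action",
    "State",
    "Transition",
    "StepResult",
    "TaskMDP",
]


class ConfigurationError(ValueError):
    """An invalid task or parameter configuration."""


class UnknownStateError(KeyError):
    """A state id that does not belong to the task."""


class Feature(str, Enum):
    """A salient environmental element that can carry motivational value."""

    K = "K"  #: negative key light (pecking it cancels the scheduled reward)
    I = "I"  #: intermittent irrelevant key light (pecks have no effect)  # noqa: E741
    C = "C"  #: continuous key light, lit across trials and the ITI
    M = "M"  #: food magazine, present in every state
    F = "F"  #: delivered food
    NULL = "-"  #: focus of exploratory actions; never carries value


#: Features that are key lights; an ``eng`` action on one of these is a peck.
KEY_FEATURES = frozenset({Feature.K, Feature.I, Feature.C})


class ActionKind(str, Enum):
    ENG = "eng"  #: engage the proximal stimulus
    NGO = "ngo"  #: refrain from engaging the proximal stimulus
    GO = "go"  #: approach a stimulus
    EXP = "exp"  #: explore (no stimulus focus)
    EAT = "eat"  #: consume delivered food


@dataclass(frozen=True)
class Action:
    """A feature-focused action.

    ``path`` names the key-light path the action belongs to (``None`` for the
    always-available core of the task); actions on inactive paths are hidden
    from the agent.
    """

    name: str
    kind: ActionKind
    focus: Feature
    path: Optional[Feature] = None

    def __post_init__(self) -> None:
        if self.kind is ActionKind.EXP and self.focus is not Feature.NULL:
            raise ConfigurationError("explore actions must focus the null feature")
        if self.kind is ActionKind.EAT and self.focus is not Feature.F:
            raise ConfigurationError("eat actions must focus the food feature")
        if self.kind in (ActionKind.ENG, ActionKind.NGO) and self.focus is Feature.NULL:
            raise ConfigurationError("eng/ngo actions must focus a stimulus")


@dataclass(frozen=True)
class State:
    """A task state: an id plus the set of value-bearing features it contains."""

    id: str
    features: frozenset = frozenset()
    initial: bool = False
    terminal: bool = False


@dataclass(frozen=True)
class Transition:
    """Deterministic successor of a (state, action) pair."""

    next: str
    event: str = "none"  #: one of {"CS", "US", "omission", "none"}
    rewarded: bool = False


@dataclass(frozen=True)
class StepResult:
    state: State
    reward: float
    event: str
    ends_trial: bool


def _as_feature(value: Union[str, Feature]) -> Feature:
    try:
        return Feature(value)
    except ValueError:
        raise ConfigurationError(f"unknown feature {value!r}") from None


class TaskMDP:
    """Finite-horizon factored MDP with switchable key-light paths.

    Parameters
    ----------
    states
        All task states; exactly one must be flagged ``initial``.
    actions
        Mapping of state id to the actions defined there (active or not).
    transitions
        Deterministic successors for every (state id, action name) pair
        *except* ``eng`` at a key's close-state, whose routing depends on
        which key currently carries the omission contingency.
    key_paths
        For each key feature, the ids of its close-state (where ``eng``/``ngo``
        are offered) and its post-withholding state (food delivered, far from
        the magazine).
    reward_magnitude
        Reward delivered by the ``eat`` action; all other transitions pay 0.
    active, negative
        Initially active keys and the key (if any) whose engagement triggers
        reward omission.
    """

    def __init__(
        self,
        name: str,
        states: Iterable[State],
        actions: Mapping[str, Iterable[Action]],
        transitions: Mapping[tuple, Transition],
        key_paths: Mapping[Feature, Mapping[str, str]],
        reward_magnitude: float = 1.0,
        active: Optional[Iterable[Union[str, Feature]]] = None,
        negative: Optional[Union[str, Feature]] = Feature.K,
    ) -> None:
        self.name = name
        self.states = {s.id: s for s in states}
        self._actions = {sid: tuple(acts) for sid, acts in actions.items()}
        self._base_transitions = dict(transitions)
        self.key_paths = {_as_feature(k): dict(v) for k, v in key_paths.items()}
        if reward_magnitude < 0:
            raise ConfigurationError("reward_magnitude must be nonnegative")
        self.reward_magnitude = float(reward_magnitude)

        initials = [s for s in self.states.values() if s.initial]
        if len(initials) != 1:
            raise ConfigurationError("exactly one state must be initial")
        self._initial_id = initials[0].id
        for s in self.states.values():
            if Feature.M not in s.features:
                raise ConfigurationError(f"magazine missing from state {s.id}")

        self._active: frozenset = frozenset()
        self._negative: Optional[Feature] = None
        self._trans: dict = {}
        self.set_phase(active if active is not None else self.key_paths, negative)

    # -- phase control ---------------------------------------------------

    @property
    def keys(self) -> frozenset:
        """All key features defined in this task."""
        return frozenset(self.key_paths)

    @property
    def active_keys(self) -> frozenset:
        return self._active

    @property
    def negative_key(self) -> Optional[Feature]:
        return self._negative

    def set_phase(
        self,
        active: Iterable[Union[str, Feature]],
        negative: Optional[Union[str, Feature]] = None,
    ) -> "TaskMDP":
        """Activate a set of keys and designate the omission-scheduled one.

        The change is silent from the agent's point of view: nothing in its
        learned model or values is touched, only the task's routing.  Returns
        ``self`` for chaining.
        """
        active_set = frozenset(_as_feature(k) for k in active)
        unknown = active_set - self.keys
        if unknown:
            raise ConfigurationError(
                f"keys {sorted(k.value for k in unknown)} not defined in task {self.name}"
            )
        if not active_set:
            raise ConfigurationError("at least one key path must remain active")
        neg = _as_feature(negative) if negative is not None else None
        if neg is not None and neg not in active_set:
            raise ConfigurationError("the negative key must be an active key")
        self._active = active_set
        self._negative = neg

        trans = dict(self._base_transitions)
        for key, path in self.key_paths.items():
            close = path["close"]
            if key is neg:
                trans[(close, "eng")] = Transition(self._initial_id, "omission")
            else:
                trans[(close, "eng")] = Transition(path["post"])
        self._trans = trans
        return self

    # -- dynamics --------------------------------------------------------

    @property
    def initial_state(self) -> State:
        return self.states[self._initial_id]

    def _resolve(self, s: Union[str, State]) -> State:
        sid = s.id if isinstance(s, State) else s
        try:
            return self.states[sid]
        except KeyError:
            raise UnknownStateError(sid) from None

    def available_actions(self, s: Union[str, State]) -> list:
        """Actions offered in ``s`` under the current phase (active paths only)."""
        state = self._resolve(s)
        acts = [
            a
            for a in self._actions.get(state.id, ())
            if a.path is None or a.path in self._active
        ]
        if not acts:
            raise ConfigurationError(f"no available action in state {state.id}")
        return acts

    def step(self, s: Union[str, State], a: Action) -> StepResult:
        """Deterministically apply ``a`` in ``s``.

        Only the ``eat`` action pays a reward; re-entering the start state
        ends the trial.
        """
        state = self._resolve(s)
        if a not in self.available_actions(state):
            raise ValueError(f"action {a.name!r} is not available in state {state.id}")
        tr = self._trans[(state.id, a.name)]
        reward = self.reward_magnitude if tr.rewarded else 0.0
        ends = tr.next == self._initial_id
        return StepResult(self.states[tr.next], reward, tr.event, ends)

    def feature_set(self, s: Union[str, State]) -> frozenset:
        """Value-bearing features of ``s`` under the current phase.

        Inactive key lights are absent everywhere; the continuous key, when
        active, is present in every state (including the start state and the
        ITI that follows a trial).
        """
        state = self._resolve(s)
        feats = state.features - (KEY_FEATURES - self._active)
        if Feature.C in self._active:
            feats = feats | {Feature.C}
        return feats

    # -- validation ------------------------------------------------------

    def reachable_states(self) -> set:
        """Ids of states reachable from the start under the current phase."""
        seen = {self._initial_id}
        stack = [self._initial_id]
        while stack:
            sid = stack.pop()
            for a in self.available_actions(sid):
                nxt = self._trans[(sid, a.name)].next
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def max_episode_length(self) -> int:
        """Longest trial, in steps, under the current phase.

        Raises :class:`ConfigurationError` if some action sequence never
        returns to the start state (the task must be finite-horizon).
        """
        memo: dict = {}

        def depth(sid: str, on_path: frozenset) -> int:
            if sid in memo:
                return memo[sid]
            if sid in on_path:
                raise ConfigurationError(f"cycle through {sid} never ends the trial")
            best = 0
            for a in self.available_actions(sid):
                nxt = self._trans[(sid, a.name)].next
                if nxt == self._initial_id:
                    best = max(best, 1)
                else:
                    best = max(best, 1 + depth(nxt, on_path | {sid}))
            memo[sid] = best
            return best

        return depth(self._initial_id, frozenset())

    def validate(self) -> None:
        """Check totality, episode boundedness and reward placement."""
        for sid in self.reachable_states():
            acts = self.available_actions(sid)  # raises if empty
            for a in acts:
                if (sid, a.name) not in self._trans:
                    raise ConfigurationError(f"missing transition for ({sid}, {a.name})")
                tr = self._trans[(sid, a.name)]
                if tr.rewarded and a.kind is not ActionKind.EAT:
                    raise ConfigurationError("only eat transitions may be rewarded")
        self.max_episode_length()

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reward_magnitude": self.reward_magnitude,
            "active": sorted(k.value for k in self._active),
            "negative": self._negative.value if self._negative else None,
            "states": [
                {
                    "id": s.id,
                    "features": sorted(f.value for f in s.features),
                    "initial": s.initial,
                    "terminal": s.terminal,
                }
                for s in self.states.values()
            ],
            "actions": {
                sid: [
                    {
                        "name": a.name,
                        "kind": a.kind.value,
                        "focus": a.focus.value,
                        "path": a.path.value if a.path else None,
                    }
                    for a in acts
                ]
                for sid, acts in self._actions.items()
            },
            "transitions": [
                {
                    "state": sid,
                    "action": aname,
                    "next": tr.next,
                    "event": tr.event,
                    "rewarded": tr.rewarded,
                }
                for (sid, aname), tr in self._base_transitions.items()
            ],
            "key_paths": {
                k.value: dict(v) for k, v in self.key_paths.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TaskMDP":
        states = [
            State(
                id=s["id"],
                features=frozenset(_as_feature(f) for f in s["features"]),
                initial=s.get("initial", False),
                terminal=s.get("terminal", False),
            )
            for s in data["states"]
        ]
        actions = {
            sid: [
                Action(
                    name=a["name"],
                    kind=ActionKind(a["kind"]),
                    focus=_as_feature(a["focus"]),
                    path=_as_feature(a["path"]) if a.get("path") else None,
                )
                for a in acts
            ]
            for sid, acts in data["actions"].items()
        }
        transitions = {
            (t["state"], t["action"]): Transition(
                next=t["next"],
                event=t.get("event", "none"),
                rewarded=t.get("rewarded", False),
            )
            for t in data["transitions"]
        }
        return cls(
            name=data["name"],
            states=states,
            actions=actions,
            transitions=transitions,
            key_paths=data["key_paths"],
            reward_magnitude=data.get("reward_magnitude", 1.0),
            active=data.get("active"),
            negative=data.get("negative"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskMDP":
        return cls.from_dict(yaml.safe_load(text))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaskMDP):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"TaskMDP({self.name!r}, {len(self.states)} states, "
            f"active={{{', '.join(sorted(k.value for k in self._active))}}}, "
            f"negative={self._negative.value if self._negative else None})"
        )
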