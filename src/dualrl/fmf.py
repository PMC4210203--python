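"""Feature-model-free system: motivational values over stimuli.

Instead of valuing abstract states, this system caches a value V(f) on each
environmental feature (key lights, magazine, food).  After an action focused
on feature f = f(s,a) leads to state s' and reward r, the reward prediction
error is

    δ = r + γ max_{f' ∈ s'} V(f') − V(f)

(the most valued feature of the new state is used for the bootstrap, zero if
the trial ended), and V(f) is nudged by α·δ.  δ is the model's proxy for
phasic dopamine: zero when an event is fully anticipated, positive when it is
better than expected, negative on reward omission.

Features that stay present through the inter-trial interval (the magazine,
and the continuous key when lit) lose part of their acquired value at each
trial end: V ← (1 − u)·V, with one shrinkage factor per stimulus.  This is
what keeps the magazine — and, in the relevant protocols, the continuous
key — less attractive than key lights that are time-locked to reward.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional

from .mdp import ConfigurationError, Feature

__all__ = ["FeatureValues", "RPERecord", "rpe", "iti_decay"]


class FeatureValues:
    """Per-feature value table with TD updates.

    The null feature (focus of exploratory actions) is pinned at 0 and can
    never be updated.
    """

    def __init__(
        self, alpha: float = 0.15, init: Optional[Mapping[Feature, float]] = None
    ) -> None:
        if not 0 < alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        self.alpha = alpha
        self._v: Dict[Feature, float] = {f: 0.0 for f in Feature}
        if init:
            for f, v in init.items():
                if Feature(f) is Feature.NULL:
                    raise ValueError("the null feature cannot carry value")
                self._v[Feature(f)] = float(v)

    def __getitem__(self, f: Feature) -> float:
        return self._v[Feature(f)]

    def update(self, f: Feature, delta: float, alpha: Optional[float] = None) -> None:
        """V(f) ← V(f) + α·δ.  Updating the null feature is a contract violation."""
        f = Feature(f)
        if f is Feature.NULL:
            raise ValueError("the null feature is never updated")
        self._v[f] += (self.alpha if alpha is None else alpha) * delta

    def set(self, f: Feature, value: float) -> None:
        f = Feature(f)
        if f is Feature.NULL:
            raise ValueError("the null feature cannot carry value")
        self._v[f] = float(value)

    def as_dict(self) -> Dict[str, float]:
        return {f.value: v for f, v in self._v.items() if f is not Feature.NULL}

    def copy(self) -> "FeatureValues":
        out = FeatureValues(self.alpha)
        out._v = dict(self._v)
        return out

    def __repr__(self) -> str:
        vals = ", ".join(f"{f.value}={v:.3f}" for f, v in self._v.items() if f is not Feature.NULL)
        return f"FeatureValues({vals})"


def rpe(
    values: FeatureValues,
    focus: Feature,
    next_features: Optional[Iterable[Feature]],
    reward: float,
    gamma: float,
) -> float:
    """Reward prediction error for an action focused on ``focus``.

    ``next_features`` is the feature set of the successor state, or ``None``
    when the trial ended (zero bootstrap).
    """
    bootstrap = 0.0
    if next_features is not None:
        bootstrap = gamma * max((values[f] for f in next_features), default=0.0)
    return reward + bootstrap - values[focus]


def iti_decay(
    values: FeatureValues,
    present: Iterable[Feature],
    u_mag: float,
    u_cont: float,
) -> FeatureValues:
    """Degrade values of stimuli that persist through the inter-trial interval.

    V(M) ← (1−u_mag)·V(M) always (the magazine is never removed); the
    continuous key decays by (1−u_cont) only when it is part of ``present``.
    A low u means a low impact of the ITI on the stimulus's value.
    """
    for u, name in ((u_mag, "u_mag"), (u_cont, "u_cont")):
        if not 0 <= u <= 1:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    present = {Feature(f) for f in present}
    values.set(Feature.M, (1.0 - u_mag) * values[Feature.M])
    if Feature.C in present:
        values.set(Feature.C, (1.0 - u_cont) * values[Feature.C])
    return values


class RPERecord:
    """One tagged prediction error: trial index, event tag and δ."""

    __slots__ = ("trial", "event", "delta")

    def __init__(self, trial: int, event: str, delta: float) -> None:
        self.trial = trial
        self.event = event
        self.delta = delta

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RPERecord):
            return NotImplemented
        return (self.trial, self.event, self.delta) == (
            other.trial,
            other.event,
            other.delta,
        )

    def __repr__(self) -> str:
        return f"RPERecord(trial={self.trial}, event={self.event!r}, delta={self.delta:.4f})"
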