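"""Model-based system: world-model learning and exact value iteration.

The agent maintains visit counts over observed transitions, from which it
estimates a transition function T̂(s,a,s') = N(s,a,s')/N(s,a) and a reward
function R̂(s,a,s') as the running mean of observed rewards.  State-action
values solve the Bellman fixed point on the *learned* model,

    Q(s,a) = Σ_s' T̂(s,a,s') [ R̂(s,a,s') + γ max_b Q(s',b) ],

with a zero bootstrap past the end of a trial (finite-horizon episodes), and
the advantage of an action is its Q-value relative to the best available one,

    A(s,a) = Q(s,a) − max_b Q(s,b),

so that A ≤ 0 everywhere and the preferred action sits at 0.  Unvisited
state-action pairs keep Q = 0; initial behavioural tendencies are injected
through the feature values of the reactive system instead.

The tasks here are tiny (a dozen states), so the Q table is re-solved to
convergence whenever the learned model actually changes — under deterministic
transitions that stops happening once every pair has been visited.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

from .mdp import ConfigurationError

__all__ = ["WorldModel", "solve_q", "advantage", "q_to_frame"]

SAPair = Tuple[str, str]


class _SAStats:
    __slots__ = ("n", "successors")

    def __init__(self) -> None:
        self.n = 0
        # s' -> [count, reward_sum, ends_trial]
        self.successors: Dict[str, list] = {}


class WorldModel:
    """Count-based estimate of a task's transition and reward structure."""

    def __init__(self) -> None:
        self._sa: Dict[SAPair, _SAStats] = {}
        self._actions_at: Dict[str, set] = {}

    def update(self, s: str, a: str, s2: str, r: float, ends_trial: bool) -> bool:
        """Record one observed transition.

        Returns ``True`` if the estimated T̂, R̂ or episode-end flag for
        (``s``, ``a``) changed — i.e. whether replanning is warranted.
        """
        stats = self._sa.get((s, a))
        if stats is None:
            stats = self._sa[(s, a)] = _SAStats()
            self._actions_at.setdefault(s, set()).add(a)
        entry = stats.successors.get(s2)
        changed = False
        if entry is None:
            stats.successors[s2] = [1, r, ends_trial]
            changed = True
        else:
            mean = entry[1] / entry[0]
            if len(stats.successors) > 1 or mean != r or entry[2] != ends_trial:
                changed = True
            entry[0] += 1
            entry[1] += r
            entry[2] = ends_trial
        stats.n += 1
        return changed

    # -- estimates -------------------------------------------------------

    def n(self, s: str, a: str, s2: Optional[str] = None) -> int:
        stats = self._sa.get((s, a))
        if stats is None:
            return 0
        if s2 is None:
            return stats.n
        entry = stats.successors.get(s2)
        return entry[0] if entry else 0

    def transition_probs(self, s: str, a: str) -> Dict[str, float]:
        """T̂(s,a,·); empty for unvisited pairs, sums to 1 otherwise."""
        stats = self._sa.get((s, a))
        if stats is None:
            return {}
        return {s2: e[0] / stats.n for s2, e in stats.successors.items()}

    def reward_estimate(self, s: str, a: str, s2: str) -> float:
        """R̂(s,a,s'): running mean of observed rewards on that transition."""
        entry = self._sa[(s, a)].successors[s2]
        return entry[1] / entry[0]

    @property
    def state_actions(self) -> Iterable[SAPair]:
        return self._sa.keys()

    def actions_at(self, s: str) -> frozenset:
        return frozenset(self._actions_at.get(s, ()))


def solve_q(
    model: WorldModel,
    gamma: float,
    tol: float = 1e-9,
    q0: Optional[Mapping[SAPair, float]] = None,
    max_iter: int = 100_000,
) -> Dict[SAPair, float]:
    """Value iteration on the learned model, to sup-norm tolerance ``tol``.

    ``q0`` warm-starts the iteration (values for pairs no longer in the model
    are dropped; new pairs start at 0).  Successor states the model has never
    acted from bootstrap at 0, as does the end of a trial.
    """
    if not 0 <= gamma < 1:
        raise ConfigurationError("gamma must lie in [0, 1)")
    if tol <= 0:
        raise ConfigurationError("tol must be positive")
    pairs = list(model.state_actions)
    q: Dict[SAPair, float] = {p: (q0.get(p, 0.0) if q0 else 0.0) for p in pairs}
    for _ in range(max_iter):
        delta = 0.0
        for s, a in pairs:
            stats = model._sa[(s, a)]
            total = 0.0
            for s2, (count, r_sum, ends) in stats.successors.items():
                p = count / stats.n
                future = 0.0
                if not ends:
                    future = max(
                        (q[(s2, b)] for b in model.actions_at(s2)), default=0.0
                    )
                total += p * (r_sum / count + gamma * future)
            delta = max(delta, abs(total - q[(s, a)]))
            q[(s, a)] = total
        if delta < tol:
            break
    return q


def advantage(
    q: Mapping[SAPair, float], s: str, actions: Iterable
) -> Dict[str, float]:
    """Advantage row A(s,·) = Q(s,·) − max over the available actions.

    ``actions`` are the actions currently available in ``s`` (Action objects
    or names); unvisited pairs contribute Q = 0.
    """
    names = [getattr(a, "name", a) for a in actions]
    if not names:
        raise ValueError(f"state {s} has no available actions")
    row = {name: q.get((s, name), 0.0) for name in names}
    best = max(row.values())
    return {name: value - best for name, value in row.items()}


def q_to_frame(q: Mapping[SAPair, float]) -> pd.DataFrame:
    """Q (or advantage) table as a tidy (state, action, value) frame."""
    records = [
        {"state": s, "action": a, "value": v} for (s, a), v in sorted(q.items())
    ]
    return pd.DataFrame.from_records(records, columns=["state", "action", "value"])
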