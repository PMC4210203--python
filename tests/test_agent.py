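"""Integration rule, softmax choice and the trial loop."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dualrl import (
    Agent,
    AgentParams,
    ConfigurationError,
    Feature,
    FeatureValues,
    GT_PRESET,
    ST_PRESET,
    build_experiment1,
    integrated_value,
    softmax_probabilities,
)
from dualrl.mdp import Action, ActionKind


def _act(kind, focus, name="a"):
    return Action(name, kind, focus)


class TestAgentParams:
    def test_table_presets(self):
        assert (ST_PRESET.omega, ST_PRESET.v0_key, ST_PRESET.v0_mag, ST_PRESET.v0_food) == (0.9, 0.0, 0.2, 0.2)
        assert (GT_PRESET.omega, GT_PRESET.v0_key, GT_PRESET.v0_mag, GT_PRESET.v0_food) == (0.2, 0.8, 0.2, 0.2)
        for p in (ST_PRESET, GT_PRESET):
            assert (p.alpha, p.tau, p.gamma, p.u_mag, p.u_cont) == (0.15, 0.2, 0.9, 0.3, 0.2)

    def test_preset_overrides(self):
        p = AgentParams.preset("st", u_mag=0.0)
        assert p.u_mag == 0.0 and p.omega == 0.9

    @pytest.mark.parametrize(
        "kwargs", [{"omega": 1.5}, {"tau": 0.0}, {"gamma": 1.0}, {"alpha": 0.0}, {"u_mag": 2.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            AgentParams(**kwargs)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            AgentParams.preset("xx")


class TestIntegratedValue:
    def test_pure_mb_limit(self):
        v = FeatureValues(init={Feature.K: 0.6})
        for kind in (ActionKind.ENG, ActionKind.NGO, ActionKind.GO):
            assert integrated_value(-0.3, v, _act(kind, Feature.K), omega=0.0) == -0.3

    def test_pure_fmf_limit(self):
        v = FeatureValues(init={Feature.K: 0.6})
        assert integrated_value(-0.3, v, _act(ActionKind.ENG, Feature.K), omega=1.0) == 0.6

    def test_ngo_gets_no_motivational_bonus(self):
        v = FeatureValues(init={Feature.K: 0.6})
        val = integrated_value(-0.081, v, _act(ActionKind.NGO, Feature.K), omega=0.9)
        assert val == pytest.approx(-0.0081)

    def test_explore_carries_no_stimulus_value(self):
        v = FeatureValues(init={Feature.K: 0.6})
        val = integrated_value(-0.1, v, _act(ActionKind.EXP, Feature.NULL), omega=0.9)
        assert val == pytest.approx(0.1 * -0.1)


class TestSoftmax:
    def test_equal_values_give_uniform_choice(self):
        p = softmax_probabilities([0.4, 0.4, 0.4], tau=0.2)
        assert p == pytest.approx([1 / 3] * 3)

    def test_closed_form_two_actions(self):
        p = softmax_probabilities([0.6, 0.0], tau=0.2)
        assert p[0] == pytest.approx(math.e**3 / (math.e**3 + 1))
        assert p[0] == pytest.approx(0.9526, abs=1e-4)

    def test_high_temperature_limit_is_uniform(self):
        p = softmax_probabilities([5.0, -5.0, 0.0], tau=1e6)
        assert p == pytest.approx([1 / 3] * 3, abs=1e-5)

    def test_extreme_values_stay_finite(self):
        p = softmax_probabilities([1000.0, 0.0], tau=0.2)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities([], tau=0.2)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           st.floats(0.05, 10))
    def test_output_is_a_probability_simplex(self, values, tau):
        p = softmax_probabilities(values, tau)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p > 0).all()


def _policy(*names):
    order = list(names)

    def choose(state, actions):
        for name in order:
            for a in actions:
                if a.name == name:
                    return a
        raise AssertionError(f"no action among {names} in state {state.id}")

    return choose


class TestRunTrial:
    def test_forced_magazine_policy_is_rewarded_without_pecking(self):
        task, _ = build_experiment1()
        agent = Agent(task, GT_PRESET, seed=0)
        log = agent.run_trial(0, policy=_policy("goM", "ngo", "eat", "exp"))
        assert log.rewarded and log.pecked_key is None
        assert any(r.event == "US" for r in log.rpes)
        assert log.actions == ("s0:exp", "s1:goM", "s4:ngo", "s7:eat")

    def test_forced_peck_policy_triggers_omission(self):
        task, _ = build_experiment1()
        agent = Agent(task, ST_PRESET, seed=0)
        log = agent.run_trial(0, policy=_policy("goK", "eng", "exp"))
        assert not log.rewarded and log.pecked_key == "K"
        assert any(r.event == "omission" for r in log.rpes)

    def test_same_seed_gives_identical_logs(self):
        logs = []
        for _ in range(2):
            task, _ = build_experiment1()
            agent = Agent(task, ST_PRESET, seed=123)
            logs.append([agent.run_trial(t) for t in range(50)])
        for a, b in zip(*logs):
            assert a == b

    def test_iti_decay_applied_once_per_trial(self):
        task, _ = build_experiment1()
        agent = Agent(task, GT_PRESET, seed=0)
        agent.run_trial(0, policy=_policy("goM", "ngo", "eat", "exp"))
        # V(M) after the trial carries exactly one (1 - u_mag) shrinkage
        v = agent.values
        trace = FeatureValues(GT_PRESET.alpha, init={Feature.K: 0.8, Feature.M: 0.2, Feature.F: 0.2})
        g = GT_PRESET.gamma
        from dualrl import rpe
        for focus, nxt, r in [
            (Feature.M, {Feature.K, Feature.M}, 0.0),
            (Feature.M, {Feature.F, Feature.M}, 0.0),
            (Feature.F, None, 1.0),
        ]:
            trace.update(focus, rpe(trace, focus, nxt, r, g))
        assert v[Feature.M] == pytest.approx(0.7 * trace[Feature.M])
        assert v[Feature.F] == pytest.approx(trace[Feature.F])

    def test_mb_initialisation_variant_seeds_q_not_values(self):
        task, _ = build_experiment1()
        agent = Agent(task, GT_PRESET, seed=0, init_system="mb")
        assert agent.values[Feature.K] == 0.0
        assert agent.q[("s2", "eng")] == GT_PRESET.v0_key
        assert agent.q[("s7", "eat")] == GT_PRESET.v0_food


class TestLongRunBehaviour:
    def test_pure_mb_agent_maximises_reward(self):
        from dualrl import ExperimentSpec, run_population

        spec = ExperimentSpec.default("exp1", n_agents=1)
        res = run_population(spec, AgentParams(omega=0.0), base_seed=1)
        last = res.trials[res.trials.trial >= 400]
        assert last.rewarded.mean() >= 0.95

    def test_sign_trackers_peck_far_more_than_goal_trackers(
        self, st_population, gt_population
    ):
        def peck_rate(res):
            last = res.trials[res.trials.trial >= 400]
            return (last.pecked_key != "none").mean()

        assert peck_rate(st_population) > 5 * peck_rate(gt_population)
        assert peck_rate(st_population) > 0.2
        assert peck_rate(gt_population) < 0.1

    def test_neither_pecking_nor_withholding_is_absorbing(self):
        from dualrl import ExperimentSpec, run_population

        spec = ExperimentSpec.default("exp1", n_trials=1000, n_agents=1)
        res = run_population(spec, ST_PRESET, base_seed=1)
        peck = (res.trials.sort_values("trial").pecked_key != "none").to_numpy()
        for start in range(400, 1000, 200):
            window = peck[start : start + 200]
            assert window.any() and not window.all()
        switches = (peck[500:][1:] != peck[500:][:-1]).sum()
        assert switches > 20

    def test_key_value_oscillates_with_behaviour(self):
        """At steady state V(K) falls on peck trials, rises on rewarded
        withholding at the key, and the magazine stays less attractive."""
        task, _ = build_experiment1()
        agent = Agent(task, ST_PRESET, seed=3)
        rows = []
        for t in range(600):
            before = agent.values[Feature.K]
            log = agent.run_trial(t)
            rows.append(
                (
                    before,
                    agent.values[Feature.K],
                    agent.values[Feature.M],
                    log.pecked_key is not None,
                    log.rewarded,
                    any(s.startswith("s2:") for s in log.actions),
                )
            )
        steady = rows[200:]
        pecks = [r for r in steady if r[3]]
        withheld = [r for r in steady if r[5] and not r[3] and r[4]]
        assert pecks and withheld
        assert all(after < before for before, after, *_ in pecks)
        assert all(after > before for before, after, *_ in withheld)
        v_k = np.mean([r[0] for r in steady])
        v_m = np.mean([r[2] for r in steady])
        assert v_m < v_k
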