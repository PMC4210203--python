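"""Structure and dynamics of the factored task MDPs."""

import pytest

from dualrl import (
    Action,
    ActionKind,
    ConfigurationError,
    Feature,
    TaskMDP,
    UnknownStateError,
    build_experiment1,
    build_experiment3,
    build_experiment4,
)


@pytest.fixture()
def exp3_task():
    task, _ = build_experiment3()
    return task


@pytest.fixture()
def exp4_task():
    task, _ = build_experiment4("D")
    return task


class TestAvailableActions:
    @pytest.mark.parametrize(
        "sid, expected",
        [
            ("s1", {"goK", "goM", "exp"}),
            ("s2", {"eng", "ngo"}),
            ("s0", {"exp"}),
            ("s7", {"eat"}),
        ],
    )
    def test_exp1_action_sets(self, exp1_task, sid, expected):
        assert {a.name for a in exp1_task.available_actions(sid)} == expected

    def test_exp3_adds_irrelevant_key_path(self, exp3_task):
        names = {a.name for a in exp3_task.available_actions("s1")}
        assert "goI" in names and names >= {"goK", "goM", "exp"}

    def test_unknown_state_is_structural_error(self, exp1_task):
        with pytest.raises(UnknownStateError):
            exp1_task.available_actions("s99")

    def test_nonempty_in_every_reachable_state_under_all_phases(self, exp4_task):
        for active, neg in [({"K"}, "K"), ({"K", "C"}, "K"),
                            ({"K", "C", "I"}, "K"), ({"C"}, None)]:
            exp4_task.set_phase(active, neg)
            for sid in exp4_task.reachable_states():
                assert exp4_task.available_actions(sid)


class TestStep:
    def test_engaging_negative_key_omits_reward_and_ends_trial(self, exp1_task):
        eng = next(a for a in exp1_task.available_actions("s2") if a.name == "eng")
        res = exp1_task.step("s2", eng)
        assert (res.state.id, res.reward, res.event) == ("s0", 0.0, "omission")
        assert res.ends_trial

    def test_eat_is_the_only_rewarded_transition(self, exp1_task):
        eat = exp1_task.available_actions("s7")[0]
        res = exp1_task.step("s7", eat)
        assert res.reward == exp1_task.reward_magnitude and res.event == "US"
        for sid in exp1_task.states:
            for a in exp1_task.available_actions(sid):
                if a.kind is not ActionKind.EAT:
                    assert exp1_task.step(sid, a).reward == 0.0

    def test_key_onset_is_tagged_cs(self, exp1_task):
        res = exp1_task.step("s0", exp1_task.available_actions("s0")[0])
        assert (res.state.id, res.reward, res.event) == ("s1", 0.0, "CS")

    def test_unavailable_action_is_a_contract_violation(self, exp1_task):
        foreign = Action("eng", ActionKind.ENG, Feature.K)
        with pytest.raises(ValueError):
            exp1_task.step("s1", foreign)

    def test_episode_bounded_within_six_steps(self, exp1_task):
        assert exp1_task.max_episode_length() <= 6

    def test_one_reward_opportunity_per_episode(self, exp1_task):
        # every trajectory reaches s0 with total reward 0 or reward_magnitude
        def explore(sid, total):
            totals = set()
            for a in exp1_task.available_actions(sid):
                res = exp1_task.step(sid, a)
                t = total + res.reward
                if res.ends_trial:
                    totals.add(t)
                else:
                    totals |= explore(res.state.id, t)
            return totals

        assert explore("s0", 0.0) == {0.0, exp1_task.reward_magnitude}


class TestSetPhase:
    def test_deactivated_key_disappears_from_choice_set(self, exp4_task):
        exp4_task.set_phase({"K", "C"}, "K")
        assert "goI" not in {a.name for a in exp4_task.available_actions("s1")}

    def test_reversal_swaps_omission_routing(self, exp3_task):
        exp3_task.set_phase({"K", "I"}, "I")
        eng_i = next(a for a in exp3_task.available_actions("s2I") if a.name == "eng")
        eng_k = next(a for a in exp3_task.available_actions("s2") if a.name == "eng")
        assert exp3_task.step("s2I", eng_i).event == "omission"
        res = exp3_task.step("s2", eng_k)
        assert res.event != "omission" and Feature.F in res.state.features

    def test_irrelevant_key_engagement_reaches_food(self, exp3_task):
        eng_i = next(a for a in exp3_task.available_actions("s2I") if a.name == "eng")
        res = exp3_task.step("s2I", eng_i)
        assert Feature.F in res.state.features and not res.ends_trial

    def test_empty_activation_is_an_error(self, exp3_task):
        with pytest.raises(ConfigurationError):
            exp3_task.set_phase(set())

    def test_unknown_key_is_an_error(self, exp1_task):
        with pytest.raises(ConfigurationError):
            exp1_task.set_phase({"X"})
        with pytest.raises(ConfigurationError):
            exp1_task.set_phase({"I"})  # not defined in the single-key task

    def test_continuous_key_joins_every_feature_set_when_active(self, exp4_task):
        exp4_task.set_phase({"K", "C"}, "K")
        for sid in exp4_task.states:
            assert Feature.C in exp4_task.feature_set(sid)
        exp4_task.set_phase({"K"}, "K")
        for sid in exp4_task.states:
            assert Feature.C not in exp4_task.feature_set(sid)

    def test_magazine_present_in_every_state(self, exp4_task):
        for sid in exp4_task.states:
            assert Feature.M in exp4_task.feature_set(sid)


class TestSerialization:
    @pytest.mark.parametrize("builder", [
        lambda: build_experiment1()[0],
        lambda: build_experiment3()[0],
        lambda: build_experiment4("B")[0],
    ])
    def test_yaml_round_trip(self, builder):
        task = builder()
        clone = TaskMDP.from_yaml(task.to_yaml())
        assert clone == task
        assert clone.max_episode_length() == task.max_episode_length()
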