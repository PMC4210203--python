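import pytest
from hypothesis import HealthCheck, settings

from dualrl import (
    ExperimentSpec,
    GT_PRESET,
    ST_PRESET,
    WorldModel,
    build_experiment1,
    run_population,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def exp1_task():
    """Fresh single-key omission task (8 states, K negative)."""
    task, _ = build_experiment1()
    return task


@pytest.fixture()
def exp1_model(exp1_task):
    """World model that has observed every (state, action) pair once."""
    model = WorldModel()
    for sid in exp1_task.states:
        for a in exp1_task.available_actions(sid):
            res = exp1_task.step(sid, a)
            model.update(sid, a.name, res.state.id, res.reward, res.ends_trial)
    return model


@pytest.fixture(scope="session")
def exp1_spec():
    return ExperimentSpec.default("exp1")


@pytest.fixture(scope="session")
def st_population(exp1_spec):
    """8 sign-trackers over the default 500-trial single-key run."""
    return run_population(exp1_spec, ST_PRESET, base_seed=1)


@pytest.fixture(scope="session")
def gt_population(exp1_spec):
    """8 goal-trackers over the default 500-trial single-key run."""
    return run_population(exp1_spec, GT_PRESET, base_seed=1)
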