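"""Dopamine-like prediction-error traces across conditioning sessions.

Pools 8 sign-trackers and 8 goal-trackers on the single-key omission task and
prints the per-session mean reward prediction error at CS appearance (key
light on), at reward delivery (US) and at omission (key pecked, food
cancelled).  Late in training the pattern predicted for phasic dopamine
emerges: a positive burst at the CS, a smaller positive response at the US,
and a dip at omissions.
"""

from dualrl import (
    ExperimentSpec,
    GT_PRESET,
    ST_PRESET,
    rpe_summary,
    run_population,
)

spec = ExperimentSpec.default("exp1")
pooled = run_population(spec, ST_PRESET, base_seed=1).concat(
    run_population(spec, GT_PRESET, base_seed=1)
)
summary = rpe_summary(pooled)

print("session   CS        US        omission")
for session, group in summary.groupby("session"):
    row = {e: m for e, m in zip(group.event, group["mean"])}
    cs, us, om = (row.get(e, float("nan")) for e in ("CS", "US", "omission"))
    print(f"{session:4d}   {cs:+.3f}    {us:+.3f}    {om:+.3f}")
print("(mean delta per 50-trial session, 16 pooled agents)")
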