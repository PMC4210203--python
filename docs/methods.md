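# Methods

## Task model

Each conditioning trial is one episode in a small deterministic MDP with a
finite horizon.  States are sets of salient stimuli — the negative key light
K, the irrelevant key I, the continuous key C, the magazine M (present in
every state) and delivered food F — plus positional/context markers encoded
in the state ids (close to key, close to magazine, key just lit).  Every
action focuses a single feature: `go` approaches a stimulus, `eng`/`ngo`
engage or withhold from the proximal stimulus, `eat` consumes food, and
`exp` explores with no focus (the null feature, which never carries value).
One decision is made per discrete step; response latencies, within-trial
timing and multiple pecks per trial are outside the model — a peck is an
`eng` on a key feature, at most one per trial.

The single-key task has eight states: from the empty start state s0 the key
lights up (s1); the agent may approach the key (s2) and then peck — which
ends the trial unrewarded — or withhold until food appears far from the
magazine (s5); approach the magazine (s4), where engaging or not both lead
to food at the magazine (s7); or keep exploring (s3, s6) and reach the food
one step later.  Only `eat` in s7 is rewarded (magnitude 1.0 by default, so
Q-values read as discounted reward probabilities), every route returns to
s0 within at most five steps, and each trial offers exactly one reward
opportunity.  Arrival back at s0 terminates the episode (zero bootstrap in
both learning systems); s0 then doubles as the start of the next trial.

The two-key and continuous-key tasks extend this skeleton with one
additional path per key: an approach action from s1, a close-state offering
`eng`/`ngo`, and a food state leading back to the magazine.  Pecks on a key
that is not carrying the omission contingency have no effect (both `eng`
and `ngo` proceed to food).  Key paths can be activated/deactivated and the
omission contingency re-routed between phases or blocks *without touching
the agent's learned quantities*, mirroring the silent reversals of the
animal protocols.  While the continuous key is active it is a member of
every state's feature set, including the start state and the ITI.

Event tags are attached to transitions, not inferred downstream: `CS` on
the key-onset transition, `omission` on engaging the currently negative
key, `US` on the rewarded `eat`.  With values at convergence the `US`
prediction error approaches zero (food is fully anticipated by the time it
is eaten); the model's larger positive response at reward *delivery* is
visible in the δ of the withholding transition into the food state, which
is logged like every other update even though it carries no tag.

## Learning systems

**Model-based.**  Transition and reward estimates are maximum-likelihood
counts, `T̂ = N(s,a,s')/N(s,a)` and `R̂` the running mean of observed
rewards.  Q-values are re-solved by exact value iteration (sup-norm
tolerance 1e-9, warm-started) whenever an observation actually changes the
model; under the deterministic tasks this stops happening once every pair
has been seen, so exact per-step replanning is affordable.  Unvisited pairs
keep Q = 0 — no optimism; initial tendencies come from the pre-training
values instead.  Advantages are `A = Q − max Q`, non-positive with the best
action at 0.

**Feature-model-free.**  `δ = r + γ max_{f'∈s'} V(f') − V(f(s,a))`, with a
zero bootstrap at trial end, followed by `V(f) ← V(f) + αδ`.  The same α
applies to positive and negative errors.  A `ngo` action's focused feature
*is* updated (withholding at the key raises V(K), which is what re-arms the
temptation to peck); only the decision-time bonus is withheld from `ngo`.
The ITI degradation is multiplicative, `V ← (1−u)·V`, applied once per
trial end to the magazine and, when lit, the continuous key — the minimal
form under which a low u means a low revision and values stay bounded.

**Update order within a step:** world-model update → Q re-solve (if
needed) → δ on pre-update values → feature-value update.  δ must see
pre-update values; the remaining order is inconsequential and fixed for
determinism.

## Parameters

| parameter | meaning | shared default | ST | GT |
|---|---|---|---|---|
| ω | FMF weight in the integration | — | 0.9 | 0.2 |
| α | FMF learning rate | 0.15 | | |
| τ | softmax temperature (divisor) | 0.2 | | |
| γ | discount rate | 0.9 | | |
| u_M | ITI degradation of V(M) | 0.3 | | |
| u_C | ITI degradation of V(C) | 0.2 | | |
| v₀ (key/mag/food) | pre-training initial values | — | 0.0/0.2/0.2 | 0.8/0.2/0.2 |

The initial triple seeds the FMF values of the conditioned key, magazine
and food, standing in for magazine familiarisation and (for the GT profile,
which models briefly autoshaped birds) key pre-exposure; it washes out with
learning.  A constructor switch (`init_system="mb"`) seeds the Q-table
entries of actions focused on those features instead, for users who read
"pre-trained action values" as model-based; the long-run behaviour is
unaffected either way.  τ is a temperature (values are divided by it); an
inverse-gain reading would merely rescale all contrasts.

## Simulated experiments and defaults

Populations of independent agents (seeds `base_seed + i` on counter-based
Philox streams; identical inputs give bit-identical logs) run:

* **exp1** — single negative key, 8 agents × 500 trials (10 sessions of 50);
* **exp3** — negative + irrelevant key, 8 agents × 800 trials, contingency
  reversals at trials 200/400/600;
* **exp4** — protocols A–D over three 300-trial phases activating the key
  subsets (K), (K,C), (C) / (K), (K,C,I), (C) / (K,C)×2, (C) /
  (K,C,I)×2, (C); 2 agents.

Reversal schedules and run lengths are configurable; the defaults above are
the package's study conditions, long enough for the steady states to be
visible at desk scale.  The second experiment of the original omission
literature (a pure contingency control) has no builder on purpose.

## What the simulations do and do not show

The generator *is* the task model: deterministic contingencies, one
decision per step, one peck at most per trial, fixed trial structure.  Real
birds show response latencies, multiple pecks per cue presentation,
variable ITIs and key-position shifts; none of these is represented, so
quantitative peck counts are not comparable to protocols where a bird can
peck many times per trial — only the qualitative pattern (who pecks, at
which key, how preferences move after reversals) is.  Behavioural
variability here comes solely from softmax exploration and the ω/initial-
value presets, not from parameter heterogeneity across individuals.

## Numerical choices and degenerate inputs

Value iteration tolerance 1e-9; softmax stabilised by max-shift; ties in
`max` resolve to the same value so no tie-break is needed.  Empty phase
activations, unknown keys/states/protocols, non-positive tolerances,
out-of-range rates and empty analysis windows raise configuration/contract
errors rather than propagating silently.  Reward magnitude must be
non-negative; γ < 1 is required (episodes are finite anyway, but the
learned model need not know that).

## Known limitations

* δ uses a single symmetric α; asymmetric appetitive/aversive channels are
  not modelled, so omission dips may be sharper than dopamine recordings
  would show.
* ω is fixed per agent; dynamic arbitration between systems is out of
  scope.
* The MB system is tabular and exact; nothing is claimed about how a real
  animal would implement planning at this scale.
* US-tagged prediction errors decay to ~0 at convergence (see Task model);
  the reward-delivery burst the model predicts lives on the withholding
  transition.
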