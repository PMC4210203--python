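experiment: exp4
n_trials: 900
trials_per_session: 50
n_agents: 2
reversals: []
protocol: C
phase_lengths:
- 300
- 300
- 300
reward_magnitude: 1.0
schedule:
- trial: 0
  active:
  - C
  - K
  negative: K
  label: phase1
- trial: 300
  active:
  - C
  - K
  negative: K
  label: phase2
- trial: 600
  active:
  - C
  negative: null
  label: phase3
task:
  name: exp4-C
  reward_magnitude: 1.0
  active:
  - C
  - K
  negative: K
  states:
  - id: s0
    features:
    - M
    initial: true
    terminal: true
  - id: s1
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s3
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s4
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s6
    features:
    - F
    - M
    initial: false
    terminal: false
  - id: s7
    features:
    - F
    - M
    initial: false
    terminal: false
  - id: s2
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s5
    features:
    - F
    - M
    initial: false
    terminal: false
  - id: s2I
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s5I
    features:
    - F
    - M
    initial: false
    terminal: false
  - id: s2C
    features:
    - I
    - K
    - M
    initial: false
    terminal: false
  - id: s5C
    features:
    - F
    - M
    initial: false
    terminal: false
  actions:
    s0:
    - name: exp
      kind: exp
      focus: '-'
      path: null
    s1:
    - name: goK
      kind: go
      focus: K
      path: K
    - name: goI
      kind: go
      focus: I
      path: I
    - name: goC
      kind: go
      focus: C
      path: C
    - name: goM
      kind: go
      focus: M
      path: null
    - name: exp
      kind: exp
      focus: '-'
      path: null
    s3:
    - name: exp
      kind: exp
      focus: '-'
      path: null
    s4:
    - name: eng
      kind: eng
      focus: M
      path: null
    - name: ngo
      kind: ngo
      focus: M
      path: null
    s6:
    - name: goM
      kind: go
      focus: M
      path: null
    s7:
    - name: eat
      kind: eat
      focus: F
      path: null
    s2:
    - name: eng
      kind: eng
      focus: K
      path: K
    - name: ngo
      kind: ngo
      focus: K
      path: K
    s5:
    - name: goM
      kind: go
      focus: M
      path: K
    s2I:
    - name: eng
      kind: eng
      focus: I
      path: I
    - name: ngo
      kind: ngo
      focus: I
      path: I
    s5I:
    - name: goM
      kind: go
      focus: M
      path: I
    s2C:
    - name: eng
      kind: eng
      focus: C
      path: C
    - name: ngo
      kind: ngo
      focus: C
      path: C
    s5C:
    - name: goM
      kind: go
      focus: M
      path: C
  transitions:
  - state: s0
    action: exp
    next: s1
    event: CS
    rewarded: false
  - state: s1
    action: goM
    next: s4
    event: none
    rewarded: false
  - state: s1
    action: exp
    next: s3
    event: none
    rewarded: false
  - state: s3
    action: exp
    next: s6
    event: none
    rewarded: false
  - state: s4
    action: eng
    next: s7
    event: none
    rewarded: false
  - state: s4
    action: ngo
    next: s7
    event: none
    rewarded: false
  - state: s6
    action: goM
    next: s7
    event: none
    rewarded: false
  - state: s7
    action: eat
    next: s0
    event: US
    rewarded: true
  - state: s1
    action: goK
    next: s2
    event: none
    rewarded: false
  - state: s2
    action: ngo
    next: s5
    event: none
    rewarded: false
  - state: s5
    action: goM
    next: s7
    event: none
    rewarded: false
  - state: s1
    action: goI
    next: s2I
    event: none
    rewarded: false
  - state: s2I
    action: ngo
    next: s5I
    event: none
    rewarded: false
  - state: s5I
    action: goM
    next: s7
    event: none
    rewarded: false
  - state: s1
    action: goC
    next: s2C
    event: none
    rewarded: false
  - state: s2C
    action: ngo
    next: s5C
    event: none
    rewarded: false
  - state: s5C
    action: goM
    next: s7
    event: none
    rewarded: false
  key_paths:
    K:
      close: s2
      post: s5
    I:
      close: s2I
      post: s5I
    C:
      close: s2C
      post: s5C
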