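# NegEx-style negation rules: trigger cues with a token scope window,
# terminated by conjunctions and sentence boundaries.
pre_cues:
  - "no"
  - "not"
  - "denies"
  - "denied"
  - "without"
  - "negative for"
  - "absence of"
  - "free of"
post_cues:
  - "was ruled out"
  - "is absent"
  - "not present"
scope_terminators:
  - "but"
  - "however"
  - "although"
  - "except"
window: 5
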