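# Fauchère–Pliska side-chain hydrophobicity scale (octanol–water partition)
# with the default magnitude-threshold alteration rule: a substitution is an
# alteration when |delta| >= delta_threshold scale units.  Switch
# alteration_mode to "category" to flag any category-crossing substitution.
alteration_mode: threshold
delta_threshold: 1.0
values:
  W: 2.25
  I: 1.80
  F: 1.79
  L: 1.70
  C: 1.54
  M: 1.23
  V: 1.22
  Y: 0.96
  P: 0.72
  A: 0.31
  T: 0.26
  H: 0.13
  G: 0.00
  S: -0.04
  Q: -0.22
  N: -0.60
  E: -0.64
  D: -0.77
  K: -0.99
  R: -1.01
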