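params:
  sigma_inf: 5.0
  sigma_tilde: 0.0
  s: 1.0
  gamma_diff: 1.0
  tau: 1.0
schedule:
  kind: constant
  omega: 6.283185307179586
  lam0: 4.0
history:
  x0: 2.0
solver:
  dt: 0.01
  t_end: 200.0
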