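# No-release limit: long-run X/I split as the contagion rate crosses the
# tipping point r0 = beta/(delta+sigma) = beta here.
schema: 1
model: no_parole
params:
  beta: 1.0
  delta: 0.5
  sigma: 0.5
  rho_x: 0.0
  rho_c: 0.0
  eps: 0.0
  N: 120.0
criminal_fraction: 0.01
sweep:
  parameter: beta
  grid: [0.2, 0.4, 0.6, 0.8, 1.2, 1.4, 1.6, 1.8, 2.0]
seed: 0
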