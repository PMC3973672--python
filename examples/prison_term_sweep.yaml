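# Effect of prison-term length: endemic equilibrium across release rates
# rho from 10 down to 0.1 (term lengths 0.1 to 10 time units).
schema: 1
model: 5d
params:
  beta: 12.0
  eps: 0.0
  delta1: 0.5
  sigma1: 5.0
  rho: 1.0       # swept below
  nu_p: 1.0
  nu_c: 0.0
  delta2: 0.5
  sigma2: 5.0
  phi: 1.0
  N: 120.0
sweep:
  parameter: rho
  grid: [10.0, 6.81, 4.64, 3.16, 2.15, 1.47, 1.0, 0.68, 0.46, 0.32, 0.22, 0.15, 0.1]
seed: 0
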