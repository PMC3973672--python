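# Strict three-strike regime: rho3 = 0, mandatory life after the third
# conviction; above threshold (r0 ~ 2.9 here) everyone ends up in prison.
schema: 1
model: 9d
params:
  beta: 2.0
  eps: 0.0
  delta1: 0.3
  sigma1: 0.4
  rho1: 0.5
  nu_p1: 0.4
  nu_c1: 0.0
  phi1: 0.3
  delta2: 0.25
  sigma2: 0.5
  rho2: 0.4
  nu_p2: 0.5
  nu_c2: 0.0
  phi2: 0.35
  delta3: 0.2
  sigma3: 0.6
  rho3: 0.0
  N: 120.0
horizon: 1.0e5
seed: 0
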