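# Full 5-compartment model, contagion-only onset (Model 3), r0 ~ 2.38
schema: 1
model: 5d
params:
  beta: 1.0      # contagion onset rate X -> C1
  eps: 0.0       # autonomous onset (0: crime-free equilibrium exists)
  delta1: 0.3    # first-offender desistance C1 -> X
  sigma1: 0.3    # first-offender incarceration C1 -> I
  rho: 0.5       # release rate I -> R (mean term = 1/rho = 2)
  nu_p: 0.3      # recidivism propensity R -> C2
  nu_c: 0.0      # recidivism contagion coefficient
  delta2: 0.3    # recidivist desistance C2 -> R
  sigma2: 0.4    # re-incarceration C2 -> I
  phi: 0.3       # redemption R -> X
  N: 120.0
criminal_fraction: 0.01   # initial perturbation of the crime-free state
horizon: 1.0e6
seed: 0
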