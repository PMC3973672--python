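# Methods

## The model hierarchy

All models track a closed population of `N` people flowing among states of
criminal activity and incarceration.  Two axes organise the hierarchy:
the number of compartments (3, 5, 9) and whether onset of crime is purely
contagious (`eps = 0`, so a crime-free equilibrium exists) or also has an
autonomous propensity component (`eps > 0`, crime never fully disappears).

### Contagion incidence

One mechanism is shared by every model and implemented once
(`crimedyn.dynamics.contagion_incidence`): a person on the street meets
others on the street, and the chance that a contact is criminally active
is the *street fraction* of active criminals,

    onset flow  = beta * X * C_total / S ,        S = street total,
    recidivism  = nu_c * R * C_total / S + nu_p * R ,

where `C_total` sums all active-criminal compartments and `S` all
non-incarcerated ones.  The incidence is normalised by the street
population, not by `N` and not mass-action.  This is what makes the
tipping points and endemic prevalences below independent of the
population size and of the release rates, and it keeps the contagion
meaningful in the no-parole limit where the street empties out.  At
`S = 0` the incidence is defined as 0 (it is bounded by
`rate*min(X, C_total) <= rate*S`).

### State orderings and equations

* 3D (`Params3D`, state `X, C, I`):

      X' = delta*C - beta*X*C/S - eps*X + rho_x*I
      C' = beta*X*C/S + eps*X - (delta+sigma)*C + rho_c*I
      I' = sigma*C - (rho_x+rho_c)*I

  Release splits into assimilation (`rho_x`) and direct return to crime
  (`rho_c`).  Because the components sum to zero, the planar reduction
  (`rhs_reduced_2d`) replaces `X = N - C - I`.
  The no-parole limit sets `rho_x = rho_c = 0`; `I` becomes absorbing.

* 5D (`Params5D`, state `X, C1, I, R, C2`): first offenders `C1` and
  recidivists `C2` share one prison `I`, released into a reentry state
  `R` at rate `rho`; from `R` people recidivate (propensity `nu_p`,
  contagion `nu_c`) or achieve redemption (`phi`) back to `X`;
  recidivists desist to `R` at `delta2` and are re-incarcerated at
  `sigma2`.

* 9D (`Params9D`, state `X, C1, I1, R1, C2, I2, R2, C3, I3`): the same
  pipeline unrolled by incarceration spell, with per-stage desistance
  `delta_k`, incarceration `sigma_k`, release `rho_k`, and per-reentry
  recidivism `(nu_p_j, nu_c_j)` and redemption `phi_j`.  Released
  third-strikers return to `R2`.  `rho3 = 0` is the strict three-strike
  regime (`I3` absorbing).

### Symbol glossary

| package name | symbol | meaning |
|---|---|---|
| `beta` | β | contagion rate of criminal onset |
| `eps` | ε | autonomous onset propensity |
| `delta`, `delta1..3` | δ, δ₁..₃ | desistance rates |
| `sigma`, `sigma1..3` | σ, σ₁..₃ | incarceration rates |
| `rho_x`, `rho_c` | ρ₁, ρ₂ | 3D release to X / to C |
| `rho`, `rho1..3` | ρ, ρ₁..₃ | release rates (1/ρ = mean term) |
| `nu_p`, `nu_c` | νₚ, ν꜀ | recidivism propensity / contagion |
| `phi`, `phi1..2` | φ, φ₁..₂ | redemption rates |
| `N` | N | population size (conserved) |

All rates are per unit time; nothing is calibrated to data — the package
works with abstract transition parameters, and results are the structural
relationships among them.

## Tipping points

`R0` — the number of people one criminally active individual recruits
over their active career — is computed in closed form as a sum of
input/output ratios (`crimedyn.thresholds`):

    3D:  R0 = beta / (delta + sigma*w),  w = rho_x/(rho_x+rho_c)
    5D:  R0 = beta/(delta1+sigma1) * [1 + sigma1*nu/((delta2+sigma2)*phi)]
    9D:  T1 = beta/(delta1+sigma1)
         T2 = T1 * sigma1*nu1 / (phi1*(delta2+sigma2) + sigma2*nu1)
         T3 = T2 * sigma2*nu2 / (phi2*(delta3+sigma3))

with `nu = nu_p + nu_c` (the recidivism rates enter only through their
sum, although they enter the ODEs differently).  The extra `sigma2*nu1`
in the 9D second term, absent from the 5D analogue, reflects the
structural difference: in the 9D model a second incarceration removes the
offender from the first reentry loop (`I2` releases into `R2`, not `R1`),
whereas the single 5D prison recycles everyone through the same `R`.

These expressions are pinned down three independent ways, and the test
suite checks all three: (i) the endemic equilibrium derived from the
stage balances gives street non-criminal prevalence exactly `1/R0`;
(ii) the Lyapunov feasibility chain (below) is nonempty exactly when the
same expression is `< 1`; (iii) simulated orbits flip regime at the same
point across random parameter draws.

`R0` is independent of every release rate and of `eps`; with `eps > 0`
the same value separates convergence to the (bifurcated) low-crime
equilibrium from convergence to the high-crime one.

### Sensitivities

All partials of the 5D `R0` are analytic; central finite differences are
cross-checks only.  Writing `k = nu/((delta2+sigma2)*phi)`:

    dR0/dsigma1 = beta*(k*delta1 - 1)/(delta1+sigma1)^2

so the sign flips at `nu*delta1 = (delta2+sigma2)*phi`
(`condition_first_offender_benefit`): more first-offender incarceration
lowers long-run crime only while recidivism is small relative to
rehabilitation and redemption.  `dR0/d{sigma2, delta1, delta2, phi}` are
always `<= 0` and `dR0/dbeta > 0`.  Over log-uniform random draws,
`|dR0/ddelta1| > |dR0/dsigma1|` in roughly three quarters of cases
(`fraction_desistance_dominant`): desistance incentives move the tipping
point more than first-offender enforcement for most parameter choices.

## Endemic equilibria

For contagion-only onset and propensity-only recidivism (`eps = 0`,
`nu_c = 0`) the stage balances make every compartment a fixed multiple of
`C1` (5D: `C2 = sigma1*nu_p*C1/(phi*(delta2+sigma2))`,
`R = sigma1*C1/phi`, `I = (sigma1*C1+sigma2*C2)/rho`), the prevalence law
`X = S/R0` fixes `X`, and the population constraint fixes the scale.
`endemic_*` return `None` below threshold — callers can distinguish "no
endemic state exists" from a degenerate state.  "Street" always means
all compartments except the incarcerated ones (5D denominator
`X + C1 + R + C2`).

With `eps > 0` or `nu_c > 0`, `numeric_equilibrium` root-finds on the
*reduced* system obtained from the linear balances (2 unknowns for 5D, 3
for 9D; a single quadratic for 3D) rather than the full ODE fixed point —
better conditioned, and the reduction mirrors how the closed forms are
derived.  Multiple dispersed restarts (scaled by feasibility caps such as
`C1 <= N/(1 + sigma1/phi + sigma1/rho)`) guard against divergence; among
converged roots the one with the largest criminal mass is returned, since
below-threshold contagion-only systems also admit the crime-free root.

The `1/R0` prevalence identity **fails** for `nu_c > 0` (recidivism
contagion breaks the balance structure); the package exposes the measured
prevalence and the suite asserts the failure on a constructed case.

## Lyapunov certificates

For `eps = 0` a linear function `V = Σ y_i z_i` over the non-X
compartments certifies global convergence to the crime-free state if
every compartment's coefficient in `dV/dt` can be made strictly negative.
Two bounds linearise `dV/dt`: `X/S <= 1` on the onset term and
`C_total/S <= 1` on the recidivism-contagion term (the latter is why
`nu_c` and `nu_p` appear only as their sum).  The resulting bracket
inequalities chain into a single interval for one free coefficient — for
the 5D model (weights `1, yI, yR, yC2` on `C1, I, R, C2`):

    [C1]  beta + yI*sigma1 < delta1 + sigma1
    [I]   yR < yI
    [R]   yC2*nu < yR*(nu + phi)
    [C2]  beta + yI*sigma2 + yR*delta2 < yC2*(delta2 + sigma2)
    =>    beta*nu/((delta2+sigma2)*phi) < yR < (delta1+sigma1-beta)/sigma1

and the interval is nonempty **iff `R0 < 1`** — certificate feasibility
*is* the threshold condition.  Coefficients are chosen at interval
midpoints and back-substituted (deterministic, positive slack); at
`R0 = 1` the open intervals are empty and the search reports infeasible.
The 9D chain has one block per reentry stage with free coefficients the
`R1`/`R2` weights.  `verify_vdot` samples `dV/dt` at Dirichlet-uniform
states on the simplex (default 1000 points, fixed seed) as an independent
soundness check.

Strict three-strike regime: with `rho3 = 0` the `I3` column of the
linearisation is identically zero, so no certificate strict in `I3`
exists (crime-free equilibria form a continuum).  `find_certificate_9d`
then drops the absorbing `I3` from `V`; the certificate proves all other
non-X mass, in particular all criminal activity, vanishes.  Its
feasibility threshold gains a `sigma3*nu2` term in the `T3` denominator
(third-strikers never return to the street), i.e. it is slightly weaker
than `R0 < 1`; equivalence sweeps therefore sample `rho3 > 0`.

No-parole system: `V = X + C` with `dV/dt = -sigma*C <= 0` for *any*
`R0`; `no_parole_decline` verifies the monotone decline by simulation.

### Caveat: bistability under recidivism contagion

With `nu_c > 0` the recidivism-contagion term is second order at the
crime-free state, so crime-free can be *locally* stable while `R0 > 1`
(the certificate/global threshold).  Simulations confirm parameter sets
where a 1% perturbation dies out despite `R0 > 1`.  Threshold-vs-
simulation properties are therefore stated (and tested) for `nu_c = 0`,
where local and global thresholds coincide; certificate-vs-threshold
equivalence holds for any `nu_c >= 0`.

## Phase plane

The planar reduction's `dI=0` isocline is the line
`I = [sigma/(rho_x+rho_c)]*C`; the `dC=0` locus, after clearing the
street denominator, is a conic whose C-axis roots are the roots of
`p(C) = -beta*C^2 + N*(beta-eps-delta-sigma)*C + eps*N^2` (origin plus
`N*(beta-delta-sigma)/beta` when `eps = 0`; one negative root when
`eps > 0`).  The three-case classification uses the denominator-free
comparisons `beta vs delta+sigma` and
`(delta+sigma-beta)*(rho_x+rho_c) vs sigma*rho_c`; case3 (crime-free
globally stable) is algebraically equivalent to `R0 < 1`.  "Globally
stable" is spot-checked, not proved, by integrating reference orbits and
random starts; |root| below `1e-9*N` is reported as a boundary case.

## Numerical choices

* **Integration**: LSODA (stiff-capable), `rtol = 1e-9`,
  `atol = 1e-10*N`, with a terminal event at `max|dz/dt| < 1e-10*N`;
  default horizon `1e4` time units, extended (up to `3e6`) for
  near-threshold runs and for `eps > 0` three-strike absorption, whose
  timescale is `~1/eps`.  Conservation drift stays below `1e-6*N` and
  components above `-1e-9*N` (asserted in tests).
* **Outcome classification** compares the stationary final state to the
  crime-free / endemic / all-incarcerated references at `1e-3*N`;
  a horizon-hit without stationarity is labelled `undetermined`
  (CLI exit code 1), never guessed.
* **Threshold regime band**: `|R0 - 1| < 1e-9` reports "at"; simulation
  properties exclude `|R0 - 1| < 0.05`, where convergence is arbitrarily
  slow.
* **Random parameter draws** (`crimedyn.sampling`): each rate log-uniform
  on `[1e-2, 1e1]`, fixed seeds in tests.  The range spans both regimes
  of every threshold and both signs of the first-offender benefit
  condition.  `N = 120` is the default population in fixtures and
  example configs.
* **Prison-term sweep defaults** (`examples/prison_term_sweep.yaml`):
  grid `rho` from 10 to 0.1 with enforcement rates (`sigma = 5`) chosen
  so the equilibrium prison population traverses its saturation curve
  inside the grid, making the diminishing-returns flattening visible;
  the monotonicity and invariance laws hold for any above-threshold
  parameter set.  "Diminishing returns" is flagged when the largest
  per-step gain in `I` is interior to the grid and gains decline
  monotonically past it.

## What the tests do and do not show

The synthetic parameter draws exercise the models across four orders of
magnitude of rates, but they are abstract: no empirical calibration, a
homogeneous and closed population, no age/space/crime-type structure, and
fixed per-capita transition rates.  Passing tests certify the internal
mathematics (thresholds, equilibria, stability, policy monotonicities),
not predictions about any real criminal-justice system.  Stochastic and
agent-based variants are out of scope.
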