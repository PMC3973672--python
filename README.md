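# crimedyn

Compartmental dynamical-systems models of the spread of crime,
incarceration and recidivism.

Criminal activity is treated the way epidemiology treats an infection:
people become criminally active mostly through contact with the
criminally active ("contagion" of crime), desist or are incarcerated,
return from prison, and either reintegrate or recidivate.  `crimedyn`
implements a hierarchy of six such population-flow models — 3, 5 and 9
compartments, each with and without an autonomous onset propensity — and
everything their long-run analysis needs:

* exact ODE right-hand sides with built-in population conservation and a
  single shared street-normalised contagion incidence `β·X·C/S`
  (`S` = everyone not incarcerated);
* closed-form tipping points (basic reproduction ratios) with their
  input/output term decomposition, e.g. for the 5-compartment model

  ```
  R0 = β/(δ1+σ1) + β·σ1·ν / ((δ1+σ1)(δ2+σ2)φ),   ν = νp + νc ;
  ```

  `R0 < 1` tips the system to the crime-free (or low-crime) equilibrium,
  `R0 > 1` to the unique high-crime endemic equilibrium — independent of
  the prison release rate ρ and of the onset propensity ε;
* closed-form endemic equilibria obeying the SIS-style prevalence law:
  the non-incarcerated population splits into a non-criminal fraction
  `1/R0` and a criminally active fraction `1 − 1/R0`;
* constructive linear Lyapunov certificates (`V = Σ yᵢ zᵢ` over the
  non-X compartments) whose feasibility is *equivalent* to `R0 < 1`,
  plus a Monte-Carlo `dV/dt < 0` verifier;
* planar phase-portrait classification from the isocline geometry, and
  the no-parole dichotomy (everyone-in-prison vs a continuum of
  crime-free states);
* policy experiments: prison-term-length sweeps (release-rate invariance
  of prevalence, rising prison population with diminishing returns),
  parole elimination, three-strike sentencing, and analytic parameter
  sensitivities of `R0` (notably the sign flip of `∂R0/∂σ1` at
  `ν·δ1 = (δ2+σ2)·φ`: incarcerating more first-time offenders backfires
  once recidivism outweighs rehabilitation and redemption).

It is aimed at researchers in mathematical sociology/criminology and
epidemiological modelling who want a tested reference implementation of
these models for analysis, teaching, or as a baseline for empirically
calibrated extensions.

## Worked example

```python
import crimedyn as cd

p = cd.Params5D(beta=1.0, eps=0.0, delta1=0.3, sigma1=0.3, rho=0.5,
                nu_p=0.3, nu_c=0.0, delta2=0.3, sigma2=0.4, phi=0.3, N=120.0)

rep = cd.r0_5d(p)
print("r0 =", rep.r0)
for k, v in rep.terms:
    print(" ", k, "=", round(v, 6))
eq = cd.endemic_5d(p)
print("endemic state:", {k: round(v, 3) for k, v in zip(cd.COMPARTMENTS["5d"], eq.state)})
print("street non-criminal prevalence:", round(eq.street_noncriminal_prevalence, 6),
      "= 1/r0:", round(1 / rep.r0, 6))
traj = cd.integrate("5d", p, cd.default_init("5d", p), horizon=1e6)
print("simulated outcome:", cd.classify_outcome(traj, p).label)
```

prints

```
r0 = 2.380952380952381
  onset X->C1 = 1.666667
  recidivism loop X->C2 = 0.714286
endemic state: {'X': 41.137, 'C1': 23.392, 'I': 22.055, 'R': 23.392, 'C2': 10.025}
street non-criminal prevalence: 0.42 = 1/r0: 0.42
simulated outcome: high_crime
```

(Compartments: X not criminally active, C1 first-time active, I
incarcerated, R recently released, C2 recidivist.)

The tipping point is 2.38 (1.67 from first-time onset, 0.71 from the
recidivism loop), so a 1% criminally-active perturbation of the 120-person
crime-free state converges to the endemic equilibrium, where 42% of the
98 people on the street (`= 1/R0`) are not criminally active.  Dropping
the contagion rate to `beta=0.25` puts `R0 = 0.595 < 1`, and the package
constructs the global-stability certificate

```
V = C1 + 0.9643*I + 0.7619*R + 1.3793*C2      (slack 0.0434)
```

whose derivative is negative along all solutions: crime dies out from any
starting point.

## Command line

Each subcommand reads a small YAML config (see `examples/`) and writes a
`summary.json` (plus `trajectory.csv` for simulations); exit code 0/1/2 =
ok/undetermined/error.

```sh
crimedyn r0          examples/full_5d.yaml          --out-dir out/
crimedyn equilibrium examples/full_5d.yaml          --out-dir out/
crimedyn certify     examples/full_5d.yaml          --out-dir out/
crimedyn simulate    examples/full_5d.yaml          --out-dir out/
crimedyn sweep       examples/prison_term_sweep.yaml --out-dir out/
crimedyn sweep       examples/no_parole_sweep.yaml  --out-dir out/
crimedyn three-strike examples/three_strike.yaml    --out-dir out/
```

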