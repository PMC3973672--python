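"""Integration, long-run outcome classification and the policy experiments.

Integration uses a stiff-capable adaptive solver (LSODA) with an event
that stops the run once the dynamics are stationary (max |dz/dt| below
1e-10*N by default).  A run that hits its horizon without reaching
stationarity is classified as *undetermined* rather than guessed at.

The policy experiments reproduce the long-run laws of the model family:

* :func:`prison_term_sweep` — equilibrium compartments across a grid of
  release rates: the tipping point and the street prevalences never move,
  the prison population grows as terms lengthen while every other
  compartment shrinks, with diminishing returns;
* :func:`no_parole_r0_sweep` — the discontinuous change in the long-run
  X/I split as the no-parole system crosses its threshold;
* :func:`three_strike_experiment` — the strict three-strike regime
  (rho3 = 0): everyone in prison above threshold, no criminals below,
  and universal lifetime incarceration whenever autonomous onset exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import Params3D, Params5D, Params9D, Trajectory, COMPARTMENTS, state_array
from .dynamics import rhs_raw
from .thresholds import r0_3d, r0_5d, r0_9d
from .equilibria import endemic_3d, endemic_5d, endemic_9d, numeric_equilibrium

__all__ = [
    "integrate",
    "OutcomeClassification",
    "classify_outcome",
    "SweepResult",
    "prison_term_sweep",
    "no_parole_r0_sweep",
    "three_strike_experiment",
    "default_init",
]

#: stationarity threshold, as a multiple of N, and the default horizon
STATIONARY_TOL = 1e-10
DEFAULT_HORIZON = 1e4

_R0 = {"3d": r0_3d, "no_parole": r0_3d, "5d": r0_5d, "9d": r0_9d}
_CRIMINAL = {"3d": [1], "no_parole": [1], "reduced_2d": [0],
             "5d": [1, 4], "9d": [1, 4, 7]}
_INCARC = {"3d": [2], "no_parole": [2], "reduced_2d": [1],
           "5d": [2], "9d": [2, 5, 8]}


def default_init(model: str, params, criminal_fraction: float = 0.01) -> np.ndarray:
    """Crime-free state perturbed by moving a fraction of X into C/C1."""
    names = COMPARTMENTS[model]
    N = params.N
    state = np.zeros(len(names))
    state[0] = (1 - criminal_fraction) * N
    state[1] = criminal_fraction * N
    return state


def integrate(model: str, params, init, horizon: float = DEFAULT_HORIZON,
              rtol: float = 1e-9, atol: float | None = None,
              stop_at_stationary: bool = True,
              stationary_tol: float = STATIONARY_TOL) -> Trajectory:
    """Integrate a model with conservation-preserving tolerances.

    Stops early (event) once max |dz/dt| < stationary_tol * N.  Raises on
    integrator failure.
    """
    init = state_array(model, init)
    if np.any(init < 0):
        raise ValueError(f"negative initial occupancy: {init}")
    rhs = rhs_raw[model]
    N = params.N
    if atol is None:
        atol = 1e-10 * N

    def f(t, y):
        return rhs(y, params)

    events = None
    if stop_at_stationary:
        def stationary(t, y):
            return float(np.max(np.abs(rhs(y, params)))) - stationary_tol * N
        stationary.terminal = True
        stationary.direction = -1
        events = stationary

    sol = solve_ivp(f, (0.0, horizon), init, method="LSODA",
                    rtol=rtol, atol=atol, events=events, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integration failed for model {model!r}: {sol.message}")
    t, y = sol.t, sol.y.T
    if sol.t_events and len(sol.t_events[0]) and sol.t_events[0][0] > t[-1]:
        t = np.append(t, sol.t_events[0][0])
        y = np.vstack([y, sol.y_events[0][0]])
    return Trajectory(t=t, y=y, model=model, params=params)


@dataclass
class OutcomeClassification:
    """Long-run regime label for an integrated orbit."""

    label: str  # crime_free | low_crime | high_crime | all_incarcerated | undetermined
    final_state: np.ndarray
    time_to_tolerance: float | None
    tolerance: float
    converged: bool
    reference: np.ndarray | None = None

    def __post_init__(self):
        if self.label == "undetermined" and self.converged:
            raise ValueError("undetermined outcomes cannot be converged")


def _is_stationary(traj: Trajectory, params, tol: float) -> bool:
    d = rhs_raw[traj.model](traj.final_state, params)
    return float(np.max(np.abs(d))) < tol * params.N


def classify_outcome(traj: Trajectory, params, tol: float = 1e-3) -> OutcomeClassification:
    """Label the long-run outcome of a trajectory against model references.

    References: the crime-free state (eps = 0 only), the endemic /
    low-crime / high-crime equilibrium, and the all-incarcerated state.
    ``tol`` is the matching tolerance as a fraction of N.  A horizon-hit
    without stationarity yields label ``undetermined`` (converged=False)
    rather than a guess.
    """
    model, N = traj.model, params.N
    final = traj.final_state
    if not _is_stationary(traj, params, STATIONARY_TOL * 10):
        return OutcomeClassification(
            label="undetermined", final_state=final, time_to_tolerance=None,
            tolerance=tol, converged=False,
        )
    t_end = float(traj.t[-1])
    non_incarcerated = float(np.sum(final)) - sum(final[i] for i in _INCARC[model])
    if non_incarcerated < tol * N:
        return OutcomeClassification(
            label="all_incarcerated", final_state=final, time_to_tolerance=t_end,
            tolerance=tol, converged=True,
        )
    criminal = sum(final[i] for i in _CRIMINAL[model])
    if params.eps == 0 and criminal < tol * N:
        return OutcomeClassification(
            label="crime_free", final_state=final, time_to_tolerance=t_end,
            tolerance=tol, converged=True,
        )
    ref = None
    r0 = _R0[model](params).r0
    if model in ("3d", "5d", "9d"):
        try:
            eq = numeric_equilibrium(model, params)
            ref = eq.state
        except (ValueError, RuntimeError):
            ref = None
    if ref is not None and float(np.max(np.abs(final - ref))) < tol * N:
        label = ("high_crime" if r0 > 1 else "low_crime") if params.eps > 0 else "high_crime"
        return OutcomeClassification(
            label=label, final_state=final, time_to_tolerance=t_end,
            tolerance=tol, converged=True, reference=ref,
        )
    return OutcomeClassification(
        label="undetermined", final_state=final, time_to_tolerance=None,
        tolerance=tol, converged=False, reference=ref,
    )


# ---------------------------------------------------------------------------
# policy experiments
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-point equilibria and laws along a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    states: np.ndarray          # one equilibrium state per grid point
    r0_values: np.ndarray
    prevalences: np.ndarray     # street non-criminal fraction per point
    classifications: list[str]
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.diff(self.grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("sweep grid must be strictly monotone")


def prison_term_sweep(params: Params5D, rho_grid) -> SweepResult:
    """Endemic equilibrium of the 5D model across release rates.

    The grid conventionally runs from rho = 10 down to 0.1 (term lengths
    from 0.1 to 10 time units).  R0 and the street prevalence are
    rho-free; as rho decreases the equilibrium prison population I rises
    and X, C1, R, C2 all fall, with shrinking marginal gains in I per
    log-step once prison holds most of the population.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    states, r0s, prevs, kinds = [], [], [], []
    for rho in rho_grid:
        p = params.replace(rho=float(rho))
        if p.eps == 0 and p.nu_c == 0:
            eq = endemic_5d(p)
            if eq is None:
                raise ValueError("prison_term_sweep needs r0 > 1 (endemic regime)")
        else:
            eq = numeric_equilibrium("5d", p)
        states.append(eq.state)
        r0s.append(r0_5d(p).r0)
        prevs.append(eq.street_noncriminal_prevalence)
        kinds.append(eq.kind)
    states = np.array(states)
    order = np.argsort(rho_grid)[::-1]  # decreasing rho = lengthening terms
    I = states[order, 2]
    others = states[order][:, [0, 1, 3, 4]]
    gains = np.diff(I)
    imax = int(np.argmax(gains))
    flags = {
        "I_increasing_as_rho_decreases": bool(np.all(np.diff(I) > 0)),
        "others_decreasing_as_rho_decreases": bool(np.all(np.diff(others, axis=0) < 0)),
        "r0_constant": bool(np.ptp(r0s) < 1e-12 * max(r0s)),
        "prevalence_constant": bool(np.ptp(prevs) < 1e-12),
        # marginal gains in I per grid step eventually shrink: the largest
        # gain is interior and gains decline monotonically past it
        "diminishing_returns": bool(len(gains) > 1 and imax < len(gains) - 1
                                    and np.all(np.diff(gains[imax:]) < 0)),
    }
    return SweepResult(
        parameter="rho", grid=rho_grid, states=states, r0_values=np.array(r0s),
        prevalences=np.array(prevs), classifications=kinds, flags=flags,
    )


def no_parole_r0_sweep(params: Params3D, beta_grid, criminal_fraction: float = 0.01,
                       horizon: float = 1e5) -> SweepResult:
    """Long-run (X, C, I) of the no-parole system across contagion rates.

    beta is a linear multiple of R0 (R0 = beta/(delta+sigma)).  Above
    threshold the entire population ends up incarcerated; below it, the
    population splits between X and I with the final prison count
    decreasing as R0 decreases.
    """
    p0 = params
    if not p0.is_no_parole or p0.eps != 0:
        raise ValueError("sweep requires zero release rates and eps = 0")
    beta_grid = np.asarray(beta_grid, dtype=float)
    states, r0s, prevs, labels = [], [], [], []
    for b in beta_grid:
        p = p0.replace(beta=float(b))
        traj = integrate("no_parole", p, default_init("no_parole", p, criminal_fraction),
                         horizon=horizon)
        final = traj.final_state
        states.append(final)
        r0s.append(r0_3d(p).r0)
        street = final[0] + final[1]
        prevs.append(final[0] / street if street > 0 else 0.0)
        labels.append(classify_outcome(traj, p).label)
    states = np.array(states)
    r0s = np.array(r0s)
    # convergence near r0 = 1 is arbitrarily slow; exclude the band from flags
    sub = r0s < 0.95
    above = r0s > 1.05
    I_sub = states[sub][np.argsort(r0s[sub])][:, 2]
    flags = {
        "above_threshold_all_incarcerated": bool(
            np.all(states[above][:, [0, 1]].sum(axis=1) < 1e-3 * p0.N)
        ) if np.any(above) else True,
        "below_threshold_crime_free": bool(
            np.all(states[sub][:, 1] < 1e-6 * p0.N)
            and np.all(states[sub][:, 0] > 0)
        ) if np.any(sub) else True,
        "I_monotone_in_r0_below_threshold": bool(np.all(np.diff(I_sub) >= -1e-9 * p0.N)),
    }
    return SweepResult(
        parameter="beta", grid=beta_grid, states=states, r0_values=r0s,
        prevalences=np.array(prevs), classifications=labels, flags=flags,
    )


@dataclass
class ThreeStrikeScenario:
    """One strict three-strike run with its long-run outcome."""

    eps: float
    r0: float
    init: np.ndarray
    outcome: OutcomeClassification


def three_strike_experiment(params: Params9D, inits=None,
                            horizon: float = 1e6) -> list[ThreeStrikeScenario]:
    """Long-run outcomes of the strict three-strike model (rho3 = 0).

    * eps = 0, R0 > 1: all orbits reach the everyone-in-prison state;
    * eps = 0, R0 < 1: no criminals in the long run, with an
      initial-condition-dependent split between X and lifetime prison I3;
    * eps > 0: everyone eventually in I3, regardless of R0 (absorption is
      slow when eps is small — hence the long default horizon).
    """
    if not params.is_three_strike:
        raise ValueError("three-strike runs require rho3 = 0")
    if inits is None:
        inits = [default_init("9d", params, 0.01),
                 default_init("9d", params, 0.30)]
    out = []
    r0 = r0_9d(params).r0
    for init in inits:
        traj = integrate("9d", params, init, horizon=horizon)
        out.append(ThreeStrikeScenario(
            eps=params.eps, r0=r0, init=np.asarray(init, dtype=float),
            outcome=classify_outcome(traj, params),
        ))
    return out
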