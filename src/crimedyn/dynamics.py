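"""Right-hand sides of the six model systems.

Every model shares one contagion mechanism: a person on the street meets
others on the street, and the probability that a contact is criminally
active is the street fraction of active criminals.  The incidence is
therefore normalised by the street population (everyone not incarcerated),

    onset flow = beta * X * C_total / S,    S = street total,

not by N and not mass-action.  This single form is what makes the tipping
points and the endemic prevalences independent of both the population size
and the release rates, and it is implemented once in
:func:`contagion_incidence` so that thresholds, equilibria and simulations
cannot drift apart.

Public ``rhs_*`` functions validate their inputs (negative occupancies are
rejected); the ``_raw`` variants skip validation and guard the 0/0 corner
of the incidence (street population numerically zero), which integrators
may probe.
"""

from __future__ import annotations

import numpy as np

from .params import Params3D, Params5D, Params9D

__all__ = [
    "contagion_incidence",
    "rhs_3d",
    "rhs_reduced_2d",
    "rhs_5d",
    "rhs_no_parole",
    "rhs_9d",
    "rhs_raw",
]


def contagion_incidence(rate: float, source: float, active: float, street: float) -> float:
    """Street-normalised incidence ``rate * source * active / street``.

    ``source`` is the occupancy of the compartment being recruited (X for
    onset, R for recidivism), ``active`` the total criminally-active street
    population, ``street`` the total non-incarcerated population.  Returns 0
    when the street is empty: the flow is bounded by ``rate*min(source,
    active)`` and vanishes with them.
    """
    if street <= 0.0:
        return 0.0
    return rate * source * active / street


def _check(state, n, name):
    state = np.asarray(state, dtype=float)
    if state.shape != (n,):
        raise ValueError(f"{name} expects {n} compartments, got shape {state.shape}")
    if np.any(state < 0):
        raise ValueError(f"negative compartment occupancy: {state}")
    return state


# ---------------------------------------------------------------------------
# 3D (Models 1 & 2)
# ---------------------------------------------------------------------------

def _rhs_3d_raw(state, p: Params3D):
    X, C, I = state
    S = X + C
    inc = contagion_incidence(p.beta, X, C, S)
    onset = inc + p.eps * X
    dX = p.delta * C - onset + p.rho_x * I
    dC = onset - (p.delta + p.sigma) * C + p.rho_c * I
    dI = p.sigma * C - (p.rho_x + p.rho_c) * I
    return np.array([dX, dC, dI])


def rhs_3d(state, params: Params3D) -> np.ndarray:
    """Flows of (X, C, I) for the 3-compartment model.

    Onset is ``beta*X*C/(X+C) + eps*X``; desistance ``delta*C``;
    incarceration ``sigma*C``; release splits into assimilation
    ``rho_x*I`` and return-to-crime ``rho_c*I``.  The three components
    sum to zero: total population is conserved.
    """
    state = _check(state, 3, "rhs_3d")
    return _rhs_3d_raw(state, params)


def _rhs_reduced_2d_raw(state, p: Params3D):
    C, I = state
    X = p.N - C - I
    S = p.N - I
    inc = contagion_incidence(p.beta, X, C, S)
    dC = inc + p.eps * X - (p.delta + p.sigma) * C + p.rho_c * I
    dI = p.sigma * C - (p.rho_x + p.rho_c) * I
    return np.array([dC, dI])


def rhs_reduced_2d(state, params: Params3D) -> np.ndarray:
    """Planar reduction of the 3D model: X eliminated via X = N - C - I."""
    state = _check(state, 2, "rhs_reduced_2d")
    C, I = state
    if C + I > params.N * (1 + 1e-12):
        raise ValueError(f"C + I = {C + I!r} exceeds N = {params.N!r}")
    return _rhs_reduced_2d_raw(state, params)


# ---------------------------------------------------------------------------
# No-parole limit (system with zero release)
# ---------------------------------------------------------------------------

def _rhs_no_parole_raw(state, p: Params3D):
    X, C, I = state
    S = X + C
    onset = contagion_incidence(p.beta, X, C, S) + p.eps * X
    dX = p.delta * C - onset
    dC = onset - (p.delta + p.sigma) * C
    dI = p.sigma * C
    return np.array([dX, dC, dI])


def rhs_no_parole(state, params: Params3D) -> np.ndarray:
    """Limiting model with no release from prison: I is absorbing.

    Requires ``rho_x == rho_c == 0``.  The prison population can only
    grow (dI = sigma*C >= 0); with ``eps > 0`` everyone is eventually
    incarcerated regardless of the tipping point.
    """
    if not params.is_no_parole:
        raise ValueError("no-parole dynamics require rho_x == rho_c == 0")
    state = _check(state, 3, "rhs_no_parole")
    return _rhs_no_parole_raw(state, params)


# ---------------------------------------------------------------------------
# 5D (Models 3 & 4)
# ---------------------------------------------------------------------------

def _rhs_5d_raw(state, p: Params5D):
    X, C1, I, R, C2 = state
    S = X + C1 + R + C2
    Ct = C1 + C2
    onset = contagion_incidence(p.beta, X, Ct, S) + p.eps * X
    recid = contagion_incidence(p.nu_c, R, Ct, S) + p.nu_p * R
    dX = p.delta1 * C1 + p.phi * R - onset
    dC1 = onset - (p.delta1 + p.sigma1) * C1
    dI = p.sigma1 * C1 + p.sigma2 * C2 - p.rho * I
    dR = p.rho * I + p.delta2 * C2 - recid - p.phi * R
    dC2 = recid - (p.delta2 + p.sigma2) * C2
    return np.array([dX, dC1, dI, dR, dC2])


def rhs_5d(state, params: Params5D) -> np.ndarray:
    """Flows of (X, C1, I, R, C2) for the full 5-compartment model.

    First offenders C1 arise by contagion (``beta*X*(C1+C2)/S``) or
    propensity (``eps*X``); both first offenders and recidivists are
    incarcerated into a single prison compartment I, released into the
    reentry compartment R at rate rho.  From R, people recidivate into C2
    by propensity (``nu_p``) or street contagion (``nu_c``), or achieve
    redemption (``phi``) back to X.  Components sum to zero.
    """
    state = _check(state, 5, "rhs_5d")
    return _rhs_5d_raw(state, params)


# ---------------------------------------------------------------------------
# 9D (Models 5 & 6)
# ---------------------------------------------------------------------------

def _rhs_9d_raw(state, p: Params9D):
    X, C1, I1, R1, C2, I2, R2, C3, I3 = state
    S = X + C1 + R1 + C2 + R2 + C3
    Ct = C1 + C2 + C3
    onset = contagion_incidence(p.beta, X, Ct, S) + p.eps * X
    recid1 = contagion_incidence(p.nu_c1, R1, Ct, S) + p.nu_p1 * R1
    recid2 = contagion_incidence(p.nu_c2, R2, Ct, S) + p.nu_p2 * R2
    dX = p.delta1 * C1 + p.phi1 * R1 + p.phi2 * R2 - onset
    dC1 = onset - (p.delta1 + p.sigma1) * C1
    dI1 = p.sigma1 * C1 - p.rho1 * I1
    dR1 = p.rho1 * I1 + p.delta2 * C2 - recid1 - p.phi1 * R1
    dC2 = recid1 - (p.delta2 + p.sigma2) * C2
    dI2 = p.sigma2 * C2 - p.rho2 * I2
    dR2 = p.rho2 * I2 + p.delta3 * C3 + p.rho3 * I3 - recid2 - p.phi2 * R2
    dC3 = recid2 - (p.delta3 + p.sigma3) * C3
    dI3 = p.sigma3 * C3 - p.rho3 * I3
    return np.array([dX, dC1, dI1, dR1, dC2, dI2, dR2, dC3, dI3])


def rhs_9d(state, params: Params9D) -> np.ndarray:
    """Flows of (X, C1, I1, R1, C2, I2, R2, C3, I3).

    Distinguishes first, second and third(+) incarceration spells so that
    a three-strike policy can be expressed as ``rho3 = 0`` (no release
    after the third conviction; I3 absorbing).  Released third-strikers
    (``rho3 > 0``, the leakage regime) return to the second reentry
    compartment R2.
    """
    state = _check(state, 9, "rhs_9d")
    return _rhs_9d_raw(state, params)


#: unvalidated RHS by model key, for integrators
rhs_raw = {
    "3d": _rhs_3d_raw,
    "reduced_2d": _rhs_reduced_2d_raw,
    "no_parole": _rhs_no_parole_raw,
    "5d": _rhs_5d_raw,
    "9d": _rhs_9d_raw,
}
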