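"""Endemic equilibria: closed forms for the contagion-only models and
numeric solutions for the general case.

For the contagion-only models (eps = 0, and no recidivism contagion in the
5D/9D cases) the endemic equilibrium exists iff R0 > 1 and obeys the same
prevalence law as the SIS disease model: the street (non-incarcerated)
population splits into a non-criminal fraction 1/R0 and a criminally
active fraction 1 - 1/R0.  The remaining compartments are fixed linear
multiples of C1 given by the stage balance equations, and the population
constraint pins the absolute scale.

With eps > 0 there is no crime-free equilibrium; the unique nonnegative
steady state is found numerically (low-crime below threshold, high-crime
above).  With recidivism contagion (nu_c > 0) the 1/R0 prevalence
identity fails — :func:`numeric_equilibrium` exposes the measured street
prevalence so that failure can be observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import Params3D, Params5D, Params9D
from .dynamics import rhs_raw
from .thresholds import r0_3d, r0_5d, r0_9d

__all__ = [
    "EquilibriumSolution",
    "endemic_3d",
    "endemic_5d",
    "endemic_9d",
    "numeric_equilibrium",
]

#: compartment indices counted as incarcerated, per model
_INCARCERATED = {"3d": [2], "no_parole": [2], "5d": [2], "9d": [2, 5, 8]}
#: index of X, per model
_X_INDEX = {"3d": 0, "no_parole": 0, "5d": 0, "9d": 0}


@dataclass
class EquilibriumSolution:
    """A steady state with its defect and street-prevalence summary."""

    state: np.ndarray
    model: str
    kind: str  # crime_free | endemic | low_crime | high_crime | all_incarcerated
    residual: float  # max |RHS| at the state, persons/time
    street_noncriminal_prevalence: float  # X / (N - incarcerated)

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)
        if not 0.0 <= self.street_noncriminal_prevalence <= 1.0 + 1e-12:
            raise ValueError("prevalence outside [0, 1]")


def _solution(model: str, params, state: np.ndarray, kind: str) -> EquilibriumSolution:
    res = float(np.max(np.abs(rhs_raw[model](state, params))))
    inc = sum(state[i] for i in _INCARCERATED[model])
    street = float(np.sum(state)) - inc
    prev = state[_X_INDEX[model]] / street if street > 0 else 0.0
    return EquilibriumSolution(
        state=state, model=model, kind=kind, residual=res,
        street_noncriminal_prevalence=min(prev, 1.0),
    )


# ---------------------------------------------------------------------------
# closed forms (contagion only)
# ---------------------------------------------------------------------------

def endemic_3d(params: Params3D) -> EquilibriumSolution | None:
    """Closed-form endemic equilibrium of the 3D model (Model 1).

    Requires eps = 0 and a positive release rate.  Returns ``None`` when
    R0 <= 1 (only the crime-free equilibrium exists); otherwise the unique
    positive steady state, at which the street non-criminal prevalence
    X/(X+C) equals exactly 1/R0.
    """
    if params.eps != 0:
        raise ValueError(
            "endemic_3d requires eps = 0; use numeric_equilibrium for Model 2"
        )
    if params.release_total <= 0:
        raise ValueError(
            "endemic_3d requires a positive release rate; the no-parole "
            "limit has no finite endemic state"
        )
    r0 = r0_3d(params).r0
    if r0 <= 1.0:
        return None
    prev = 1.0 / r0
    street = params.N / (1.0 + params.sigma * (1.0 - prev) / params.release_total)
    X = prev * street
    C = (1.0 - prev) * street
    I = params.N - street
    return _solution("3d", params, np.array([X, C, I]), "endemic")


def _ratios_5d(params: Params5D) -> dict[str, float]:
    """Per-C1 multiples of the other compartments at the 5D equilibrium."""
    c2 = (
        params.sigma1 * params.nu_p / (params.phi * (params.delta2 + params.sigma2))
        if params.nu_p > 0 else 0.0
    )
    r = params.sigma1 / params.phi
    i = (params.sigma1 + params.sigma2 * c2) / params.rho
    return {"C2": c2, "R": r, "I": i}


def endemic_5d(params: Params5D) -> EquilibriumSolution | None:
    """Closed-form endemic equilibrium of the 5D model (Model 3, nu_c = 0).

    The stage balances give C2, R and I as fixed multiples of C1
    (C2 = sigma1*nu_p*C1/(phi*(delta2+sigma2)), R = sigma1*C1/phi,
    I = (sigma1*C1 + sigma2*C2)/rho); the prevalence law X = S/R0 and the
    population constraint then determine the scale.  ``None`` if R0 <= 1.
    With nu_p = 0 the equilibrium collapses to the 3D form (C2 = 0).
    """
    if params.eps != 0:
        raise ValueError(
            "endemic_5d requires eps = 0; use numeric_equilibrium for Model 4"
        )
    if params.nu_c != 0:
        raise ValueError(
            "the closed form (and the 1/R0 prevalence law) holds only for "
            "nu_c = 0; use numeric_equilibrium"
        )
    if params.rho <= 0 or params.phi <= 0:
        raise ValueError("endemic_5d requires rho > 0 and phi > 0")
    r0 = r0_5d(params).r0
    if r0 <= 1.0:
        return None
    m = _ratios_5d(params)
    street_per_c1 = (1.0 + m["R"] + m["C2"]) * r0 / (r0 - 1.0)
    C1 = params.N / (street_per_c1 + m["I"])
    S = street_per_c1 * C1
    X = S / r0
    state = np.array([X, C1, m["I"] * C1, m["R"] * C1, m["C2"] * C1])
    return _solution("5d", params, state, "endemic")


def _ratios_9d(params: Params9D) -> dict[str, float]:
    p = params
    den2 = p.phi1 * (p.delta2 + p.sigma2) + p.sigma2 * p.nu_p1
    c2 = p.sigma1 * p.nu_p1 / den2 if p.nu_p1 > 0 else 0.0
    c3 = (
        c2 * p.sigma2 * p.nu_p2 / (p.phi2 * (p.delta3 + p.sigma3))
        if (p.nu_p2 > 0 and c2 > 0) else 0.0
    )
    # reentry balances: nu_p1*R1 = (delta2+sigma2)*C2 ; nu_p2*R2 = (delta3+sigma3)*C3
    r1 = (p.delta2 + p.sigma2) * c2 / p.nu_p1 if p.nu_p1 > 0 else p.sigma1 / p.phi1
    r2 = (p.delta3 + p.sigma3) * c3 / p.nu_p2 if p.nu_p2 > 0 else p.sigma2 * c2 / p.phi2
    return {
        "C2": c2, "C3": c3, "R1": r1, "R2": r2,
        "I1": p.sigma1 / p.rho1,
        "I2": p.sigma2 * c2 / p.rho2,
        "I3": p.sigma3 * c3 / p.rho3 if c3 > 0 else 0.0,
    }


def endemic_9d(params: Params9D) -> EquilibriumSolution | None:
    """Closed-form endemic equilibrium of the 9D model (Model 5, nu_c_j = 0).

    Same construction as the 5D case, with three stage blocks; street
    non-criminal fraction equals 1/R0.  Requires positive release and
    redemption rates (and rho3 > 0 if the third stage is populated).
    ``None`` if R0 <= 1.
    """
    p = params
    if p.eps != 0:
        raise ValueError("endemic_9d requires eps = 0; use numeric_equilibrium")
    if p.nu_c1 != 0 or p.nu_c2 != 0:
        raise ValueError(
            "the closed form holds only with no recidivism contagion "
            "(nu_c1 = nu_c2 = 0); use numeric_equilibrium"
        )
    if min(p.rho1, p.rho2, p.phi1, p.phi2) <= 0:
        raise ValueError("endemic_9d requires positive rho1, rho2, phi1, phi2")
    r0 = r0_9d(p).r0
    if r0 <= 1.0:
        return None
    m = _ratios_9d(p)
    if m["C3"] > 0 and p.rho3 <= 0:
        raise ValueError(
            "rho3 = 0 with a populated third stage: the strict three-strike "
            "model has no finite endemic state"
        )
    street_per_c1 = (1.0 + m["R1"] + m["C2"] + m["R2"] + m["C3"]) * r0 / (r0 - 1.0)
    inc_per_c1 = m["I1"] + m["I2"] + m["I3"]
    C1 = p.N / (street_per_c1 + inc_per_c1)
    S = street_per_c1 * C1
    X = S / r0
    state = np.array([
        X, C1, m["I1"] * C1, m["R1"] * C1, m["C2"] * C1,
        m["I2"] * C1, m["R2"] * C1, m["C3"] * C1, m["I3"] * C1,
    ])
    return _solution("9d", params, state, "endemic")


# ---------------------------------------------------------------------------
# numeric equilibria (eps >= 0, nu_c >= 0)
# ---------------------------------------------------------------------------

def _kind(params, r0: float, state: np.ndarray, criminal_idx) -> str:
    if params.eps > 0:
        return "low_crime" if r0 < 1.0 else "high_crime"
    crim = sum(state[i] for i in criminal_idx)
    return "endemic" if crim > 1e-9 * params.N else "crime_free"


def _numeric_3d(params: Params3D) -> np.ndarray:
    """Positive equilibrium of the planar reduction via its quadratic.

    Substituting the I-isocline I = s*C (s = sigma/(rho_x+rho_c)) into the
    C-isocline and clearing the street denominator leaves a quadratic in C
    whose admissible root is the equilibrium.
    """
    p = params
    if p.release_total <= 0:
        raise ValueError("numeric equilibrium needs a positive release rate")
    s = p.sigma / p.release_total
    b, eps, N = p.beta, p.eps, p.N
    # dC * (N - s*C) = 0 with I = s*C:
    # beta*C*(N-(1+s)C) + [eps*(N-(1+s)C) + (rho_c*s - delta - sigma)*C]*(N - s*C) = 0
    a2 = -b * (1 + s) + eps * s * (1 + s) - (p.rho_c * s - p.delta - p.sigma) * s
    a1 = b * N - eps * N * (1 + s) - eps * s * N + (p.rho_c * s - p.delta - p.sigma) * N
    a0 = eps * N * N
    roots = np.roots([a2, a1, a0]) if a2 != 0 else np.array([-a0 / a1])
    cmax = N / (1 + s)
    admissible = [
        float(r.real) for r in roots
        if abs(r.imag) < 1e-9 and -1e-12 * N <= r.real <= cmax * (1 + 1e-12)
    ]
    if p.eps == 0:
        admissible = [c for c in admissible if c > 1e-12 * N]
        if not admissible:  # below threshold: only the crime-free state
            return np.array([N, 0.0, 0.0])
    if not admissible:
        raise RuntimeError(f"no admissible equilibrium root found (roots={roots})")
    C = max(admissible)  # the unique positive equilibrium (largest admissible root)
    I = s * C
    return np.array([N - C - I, C, I])


def _assemble_5d(params: Params5D, C1: float, C2: float) -> np.ndarray:
    p = params
    R = p.sigma1 * C1 / p.phi
    I = (p.sigma1 * C1 + p.sigma2 * C2) / p.rho
    X = p.N - C1 - C2 - R - I
    return np.array([X, C1, I, R, C2])


def _numeric_5d(params: Params5D, guesses) -> np.ndarray:
    """Equilibrium via 2-unknown root-finding in (C1, C2).

    The linear balances R = sigma1*C1/phi and I = (sigma1*C1+sigma2*C2)/rho
    (which hold for any eps, nu_c) reduce the fixed-point problem to the
    two onset/recidivism balance equations.
    """
    p = params
    if p.phi <= 0 or p.rho <= 0:
        raise ValueError("numeric equilibrium needs phi > 0 and rho > 0")

    def fun(z):
        C1, C2 = z
        state = _assemble_5d(p, C1, C2)
        d = rhs_raw["5d"](state, p)
        return [d[1], d[4]]

    candidates = []
    for g in guesses:
        sol = optimize.root(fun, g, method="hybr", options={"xtol": 1e-13})
        if not sol.success:
            continue
        C1, C2 = sol.x
        if C1 < -1e-9 * p.N or C2 < -1e-9 * p.N:
            continue
        state = np.clip(_assemble_5d(p, max(C1, 0.0), max(C2, 0.0)), 0, None)
        if _assemble_5d(p, max(C1, 0.0), max(C2, 0.0))[0] < -1e-9 * p.N:
            continue
        res = float(np.max(np.abs(rhs_raw["5d"](state, p))))
        if res < 1e-8 * p.N:
            candidates.append((state, res))
    if not candidates:
        raise RuntimeError("5d equilibrium root-finding failed from all starts")
    # among true roots, take the one with the largest criminal mass: for
    # eps = 0 both the crime-free state and the endemic state are roots
    return max(candidates, key=lambda c: c[0][1] + c[0][4])[0]


def _assemble_9d(params: Params9D, C1: float, C2: float, C3: float) -> np.ndarray:
    p = params
    I1 = p.sigma1 * C1 / p.rho1
    I2 = p.sigma2 * C2 / p.rho2
    I3 = p.sigma3 * C3 / p.rho3
    R1 = (p.sigma1 * C1 - p.sigma2 * C2) / p.phi1
    R2 = p.sigma2 * C2 / p.phi2
    X = p.N - C1 - C2 - C3 - I1 - I2 - I3 - R1 - R2
    return np.array([X, C1, I1, R1, C2, I2, R2, C3, I3])


def _numeric_9d(params: Params9D, guesses) -> np.ndarray:
    """Equilibrium via 3-unknown root-finding in (C1, C2, C3).

    Uses the incarceration balances I_k = sigma_k C_k / rho_k and the
    reentry-block sums (R1 = (sigma1 C1 - sigma2 C2)/phi1,
    R2 = sigma2 C2 / phi2), all valid for any eps, nu_c.
    """
    p = params
    if min(p.rho1, p.rho2, p.rho3, p.phi1, p.phi2) <= 0:
        raise ValueError("numeric 9d equilibrium needs positive rho_k and phi_j")

    def fun(z):
        state = _assemble_9d(p, *z)
        d = rhs_raw["9d"](state, p)
        return [d[1], d[4], d[7]]

    candidates = []
    for g in guesses:
        sol = optimize.root(fun, g, method="hybr", options={"xtol": 1e-13})
        if not sol.success:
            continue
        if np.any(np.asarray(sol.x) < -1e-9 * p.N):
            continue
        state = _assemble_9d(p, *np.clip(sol.x, 0, None))
        if state[0] < -1e-9 * p.N or state[3] < -1e-9 * p.N:
            continue
        state = np.clip(state, 0, None)
        res = float(np.max(np.abs(rhs_raw["9d"](state, p))))
        if res < 1e-8 * p.N:
            candidates.append((state, res))
    if not candidates:
        raise RuntimeError("9d equilibrium root-finding failed from all starts")
    return max(candidates, key=lambda c: c[0][1] + c[0][4] + c[0][7])[0]


def numeric_equilibrium(model: str, params, initial_guess=None,
                        n_starts: int = 10, seed: int = 0) -> EquilibriumSolution:
    """Unique nonnegative equilibrium of the 3D, 5D or 9D model.

    Works for any eps >= 0 and nu_c >= 0 by root-finding on the reduced
    system obtained from the linear stage balances (not the full ODE
    fixed point), restarted from ``n_starts`` dispersed points.  For
    eps > 0 the result is classified ``low_crime`` (R0 < 1) or
    ``high_crime`` (R0 > 1); for eps = 0 it is the endemic state.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    if model == "3d":
        state = _numeric_3d(params)
        r0 = r0_3d(params).r0
        criminal_idx = [1]
    elif model == "5d":
        p = params
        # feasibility caps: C1 (with its induced R and I) and C2 (with its
        # induced I) cannot push the assembled state past N
        c1_cap = N / (1.0 + p.sigma1 / p.phi + p.sigma1 / p.rho)
        c2_cap = N / (1.0 + p.sigma2 / p.rho)
        guesses = [initial_guess] if initial_guess is not None else []
        guesses += [(0.5 * c1_cap, 0.1 * c2_cap), (0.1 * c1_cap, 0.5 * c2_cap)]
        guesses += [(u * c1_cap, v * c2_cap)
                    for u, v in rng.uniform(0.01, 0.95, (n_starts, 2))]
        state = _numeric_5d(params, guesses)
        r0 = r0_5d(params).r0
        criminal_idx = [1, 4]
    elif model == "9d":
        p = params
        c1_cap = N / (1.0 + p.sigma1 / p.phi1 + p.sigma1 / p.rho1)
        c2_cap = N / (1.0 + p.sigma2 / p.phi2 + p.sigma2 / p.rho2)
        c3_cap = N / (1.0 + p.sigma3 / p.rho3)
        guesses = [initial_guess] if initial_guess is not None else []
        guesses += [(0.5 * c1_cap, 0.2 * c2_cap, 0.05 * c3_cap)]
        guesses += [(u * c1_cap, u * v * c2_cap, u * v * w * c3_cap)
                    for u, v, w in rng.uniform(0.01, 0.95, (n_starts, 3))]
        state = _numeric_9d(params, guesses)
        r0 = r0_9d(params).r0
        criminal_idx = [1, 4, 7]
    else:
        raise ValueError(f"unknown model {model!r}")
    return _solution(model, params, state, _kind(params, r0, state, criminal_idx))
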