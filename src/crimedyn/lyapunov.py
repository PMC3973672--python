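"""Constructive linear Lyapunov certificates for the crime-free equilibrium.

For each contagion-only model (eps = 0) we seek a linear function

    V = sum_i  y_i * z_i,   y_i > 0,

over the non-X compartments z whose derivative along solutions is strictly
negative away from the crime-free state.  Bounding the street fractions
that appear in the contagion terms (X/S <= 1 for onset, C_total/S <= 1 for
recidivism contagion — the latter makes nu_c and nu_p enter only as their
sum) turns dV/dt into a linear form in z; V certifies global convergence
as soon as each compartment's bracketed coefficient is negative.

The bracket inequalities chain into one interval for a single free
coefficient; the interval is nonempty exactly when R0 < 1, so certificate
feasibility *is* the tipping-point condition.  Coefficients are chosen at
interval midpoints and back-substituted, which yields a deterministic
certificate with strictly positive slack whenever one exists.  At R0 = 1
the (strict, open) intervals are empty and the search reports infeasible.

The no-parole system has its own elementary certificate V = X + C with
dV/dt = -sigma*C <= 0 for every R0, verified by simulation in
:func:`no_parole_decline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isinf

import numpy as np

from .params import Params3D, Params5D, Params9D
from .dynamics import rhs_raw
from .thresholds import r0_3d, r0_5d, r0_9d

__all__ = [
    "LyapunovCertificate",
    "find_certificate_2d",
    "find_certificate_5d",
    "find_certificate_9d",
    "verify_vdot",
    "no_parole_decline",
]


@dataclass
class LyapunovCertificate:
    """Positive weights certifying global stability of the crime-free state."""

    model: str
    feasible: bool
    coefficients: dict[str, float] = field(default_factory=dict)
    slack: float = 0.0  # minimal margin of the bracket inequalities
    r0: float = float("nan")

    def __post_init__(self):
        if self.feasible:
            if not all(v > 0 for v in self.coefficients.values()):
                raise ValueError("feasible certificate needs positive coefficients")
            if not self.slack > 0:
                raise ValueError("feasible certificate needs positive slack")

    def weights(self, names) -> np.ndarray:
        return np.array([self.coefficients[n] for n in names])


def _mid(lo: float, hi: float) -> float:
    """Midpoint of an open interval; lo + max(1, lo) when unbounded above."""
    if isinf(hi):
        return lo + max(1.0, lo)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# 2D (planar reduction of the 3D model)
# ---------------------------------------------------------------------------

def find_certificate_2d(params: Params3D) -> LyapunovCertificate:
    """Certificate V = C + a*I for the planar system (eps = 0).

    The two bracket conditions are ``beta - delta - sigma + a*sigma < 0``
    (coefficient of C, after bounding X/(X+C) <= 1) and
    ``rho_c - a*(rho_x + rho_c) < 0`` (coefficient of I), i.e.

        rho_c/(rho_x+rho_c)  <  a  <  (delta + sigma - beta)/sigma,

    an interval that is nonempty iff R0 < 1; a is taken at its midpoint.
    """
    if params.eps != 0:
        raise ValueError("crime-free certificates require eps = 0")
    if params.release_total <= 0:
        raise ValueError(
            "use no_parole_decline for the zero-release system (the I "
            "coefficient cannot be made strictly negative)"
        )
    p = params
    r0 = r0_3d(p).r0
    lo = p.rho_c / p.release_total
    if p.sigma > 0:
        hi = (p.delta + p.sigma - p.beta) / p.sigma
    else:
        hi = inf if p.beta < p.delta else -inf
    if not lo < hi:
        return LyapunovCertificate(model="3d", feasible=False, r0=r0)
    a = _mid(lo, hi)
    slack = min(
        p.delta + p.sigma - p.beta - a * p.sigma,
        a * p.release_total - p.rho_c,
    )
    return LyapunovCertificate(
        model="3d", feasible=True, coefficients={"C": 1.0, "I": a},
        slack=float(slack), r0=r0,
    )


# ---------------------------------------------------------------------------
# 5D
# ---------------------------------------------------------------------------

def find_certificate_5d(params: Params5D) -> LyapunovCertificate:
    """Certificate V = C1 + yI*I + yR*R + yC2*C2 for the 5D model (eps = 0).

    Bracket conditions (normalising the C1 weight to 1, nu = nu_p + nu_c):

        [C1]  beta + yI*sigma1            < delta1 + sigma1
        [I]   yR                          < yI
        [R]   yC2*nu                      < yR*(nu + phi)
        [C2]  beta + yI*sigma2 + yR*delta2 < yC2*(delta2 + sigma2)

    Chaining them leaves one interval for yR,

        beta*nu/((delta2+sigma2)*phi)  <  yR  <  (delta1+sigma1-beta)/sigma1,

    nonempty iff R0 < 1.  yR is set at the midpoint, then yI and yC2 are
    back-substituted at the midpoints of their induced intervals.
    """
    if params.eps != 0:
        raise ValueError("crime-free certificates require eps = 0")
    p = params
    r0 = r0_5d(p).r0
    nu = p.nu
    infeasible = LyapunovCertificate(model="5d", feasible=False, r0=r0)

    lo = p.beta * nu / ((p.delta2 + p.sigma2) * p.phi) if nu > 0 else 0.0
    if p.sigma1 > 0:
        hi = (p.delta1 + p.sigma1 - p.beta) / p.sigma1
    else:
        hi = inf if p.beta < p.delta1 else -inf
    if not lo < hi:
        return infeasible
    yR = _mid(lo, hi)

    # yI in (yR, hi), also keeping the yC2 interval open:
    # beta + yI*sigma2 + yR*delta2 < yR*(nu+phi)*(delta2+sigma2)/nu
    yI_hi = hi
    if nu > 0 and p.sigma2 > 0:
        yI_hi = min(
            yI_hi,
            (yR * (nu + p.phi) * (p.delta2 + p.sigma2) / nu
             - p.beta - yR * p.delta2) / p.sigma2,
        )
    if not yR < yI_hi:
        return infeasible
    yI = _mid(yR, yI_hi)

    d_lo = (p.beta + yI * p.sigma2 + yR * p.delta2) / (p.delta2 + p.sigma2)
    d_hi = yR * (nu + p.phi) / nu if nu > 0 else inf
    if not d_lo < d_hi:
        return infeasible
    yC2 = _mid(d_lo, d_hi)

    brackets = [
        (p.delta1 + p.sigma1) - p.beta - yI * p.sigma1,
        yI - yR,
        yR * (nu + p.phi) - yC2 * nu,
        yC2 * (p.delta2 + p.sigma2) - p.beta - yI * p.sigma2 - yR * p.delta2,
    ]
    slack = float(min(brackets))
    if slack <= 0:
        return infeasible
    return LyapunovCertificate(
        model="5d", feasible=True,
        coefficients={"C1": 1.0, "I": yI, "R": yR, "C2": yC2},
        slack=slack, r0=r0,
    )


# ---------------------------------------------------------------------------
# 9D
# ---------------------------------------------------------------------------

def find_certificate_9d(params: Params9D) -> LyapunovCertificate:
    """Certificate over the eight non-X compartments of the 9D model (eps = 0).

    Same construction as the 5D chain, one block per reentry stage; the
    free coefficients are the R1 and R2 weights, each chosen at the
    midpoint of its interval, the rest back-substituted.  Feasibility is
    equivalent to R0 < 1 when rho3 > 0.

    In the strict three-strike regime (rho3 = 0) the I3 column of the
    linearisation is identically zero, so no certificate strict in I3
    exists; I3 (absorbing) is dropped from V, and the certificate then
    proves that all *other* non-X mass — in particular all criminal
    activity — converges to zero.  Its feasibility threshold is then
    slightly weaker than R0 = 1 (the T3 denominator gains sigma3*nu2,
    because third-strikers never return to the street).
    """
    if params.eps != 0:
        raise ValueError("crime-free certificates require eps = 0")
    p = params
    r0 = r0_9d(p).r0
    nu1, nu2 = p.nu1, p.nu2
    include_I3 = p.rho3 > 0
    infeasible = LyapunovCertificate(model="9d", feasible=False, r0=r0)

    # stage-3 block lower bound for w2 (the R2 weight)
    if nu2 > 0:
        if include_I3:
            W2 = p.beta * nu2 / ((p.delta3 + p.sigma3) * p.phi2)
        else:
            W2 = p.beta * nu2 / ((p.delta3 + p.sigma3) * p.phi2 + p.sigma3 * nu2)
    else:
        W2 = 0.0
    # stage-2 block lower bound for w1 (the R1 weight)
    if nu1 > 0:
        W1 = (p.beta + W2 * p.sigma2) * nu1 / (
            p.sigma2 * nu1 + p.phi1 * (p.delta2 + p.sigma2)
        )
    else:
        W1 = 0.0
    if p.sigma1 > 0:
        B1 = (p.delta1 + p.sigma1 - p.beta) / p.sigma1
    else:
        B1 = inf if p.beta < p.delta1 else -inf
    if not W1 < B1:
        return infeasible
    w1 = _mid(W1, B1)
    v1 = _mid(w1, B1)  # I1 weight, in (w1, B1)

    # stage 2: u2 (C2 weight) in ((beta + w1*delta2 + v2*sigma2)/(delta2+sigma2),
    #                             w1*(nu1+phi1)/nu1); v2 (I2 weight) > w2
    u2_hi = w1 * (nu1 + p.phi1) / nu1 if nu1 > 0 else inf
    if p.sigma2 > 0 and not isinf(u2_hi):
        V2hi = (u2_hi * (p.delta2 + p.sigma2) - p.beta - w1 * p.delta2) / p.sigma2
    else:
        V2hi = inf
    if not W2 < V2hi:
        return infeasible
    w2 = _mid(W2, V2hi)
    v2 = _mid(w2, V2hi)
    u2 = _mid((p.beta + w1 * p.delta2 + v2 * p.sigma2) / (p.delta2 + p.sigma2), u2_hi)

    # stage 3: u3 (C3 weight); v3 (I3 weight) > w2 when I3 participates
    u3_hi = w2 * (nu2 + p.phi2) / nu2 if nu2 > 0 else inf
    if include_I3:
        if p.sigma3 > 0 and not isinf(u3_hi):
            V3hi = (u3_hi * (p.delta3 + p.sigma3) - p.beta - w2 * p.delta3) / p.sigma3
        else:
            V3hi = inf
        if not w2 < V3hi:
            return infeasible
        v3 = _mid(w2, V3hi)
    else:
        v3 = 0.0
    u3_lo = (p.beta + w2 * p.delta3 + v3 * p.sigma3) / (p.delta3 + p.sigma3)
    if not u3_lo < u3_hi:
        return infeasible
    u3 = _mid(u3_lo, u3_hi)

    brackets = [
        (p.delta1 + p.sigma1) - p.beta - v1 * p.sigma1,               # C1
        (v1 - w1) * p.rho1,                                           # I1
        w1 * (nu1 + p.phi1) - u2 * nu1,                               # R1
        u2 * (p.delta2 + p.sigma2) - p.beta - w1 * p.delta2 - v2 * p.sigma2,  # C2
        (v2 - w2) * p.rho2,                                           # I2
        w2 * (nu2 + p.phi2) - u3 * nu2,                               # R2
        u3 * (p.delta3 + p.sigma3) - p.beta - w2 * p.delta3 - v3 * p.sigma3,  # C3
    ]
    coefficients = {
        "C1": 1.0, "I1": v1, "R1": w1, "C2": u2,
        "I2": v2, "R2": w2, "C3": u3,
    }
    if include_I3:
        brackets.append((v3 - w2) * p.rho3)  # I3
        coefficients["I3"] = v3
    slack = float(min(brackets))
    if slack <= 0:
        return infeasible
    return LyapunovCertificate(
        model="9d", feasible=True, coefficients=coefficients,
        slack=slack, r0=r0,
    )


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

#: compartment name order of the full state, per model
_STATE_NAMES = {
    "3d": ("X", "C", "I"),
    "5d": ("X", "C1", "I", "R", "C2"),
    "9d": ("X", "C1", "I1", "R1", "C2", "I2", "R2", "C3", "I3"),
}


def verify_vdot(cert: LyapunovCertificate, params, n_samples: int = 1000,
                seed: int = 0) -> float:
    """Max dV/dt over random states on the simplex {state >= 0, sum = N}.

    A sound certificate gives a strictly negative value (V decreases at
    every state with any mass outside X).  Returns the sampled maximum.
    """
    if not cert.feasible:
        raise ValueError("cannot verify an infeasible certificate")
    rng = np.random.default_rng(seed)
    names = _STATE_NAMES[cert.model]
    y = np.array([cert.coefficients.get(n, 0.0) for n in names[1:]])
    rhs = rhs_raw[cert.model]
    states = rng.dirichlet(np.ones(len(names)), size=n_samples) * params.N
    vmax = -np.inf
    for s in states:
        d = rhs(s, params)
        vmax = max(vmax, float(np.dot(y, d[1:])))
    return vmax


@dataclass
class NoParoleDecline:
    """Simulation evidence that V = X + C declines in the no-parole system."""

    monotone: bool  # V non-increasing along every checked orbit
    v_limits: list[float]  # final X + C per orbit
    c_limits: list[float]  # final C per orbit
    r0: float


def no_parole_decline(params: Params3D, n_orbits: int = 5, horizon: float = 2000.0,
                      seed: int = 0) -> NoParoleDecline:
    """Check that the street population X + C only declines without parole.

    dV/dt = -sigma*C <= 0 regardless of the tipping point.  Above
    threshold (or for any eps > 0) V declines to 0 — everyone ends up
    incarcerated; below threshold with eps = 0, V declines to a positive
    limit with C -> 0.
    """
    from .simulate import integrate  # local import to avoid a cycle

    if not params.is_no_parole:
        raise ValueError("no_parole_decline requires zero release rates")
    rng = np.random.default_rng(seed)
    monotone = True
    v_lims, c_lims = [], []
    for _ in range(n_orbits):
        frac = rng.dirichlet(np.ones(3)) * params.N
        traj = integrate("no_parole", params, frac, horizon=horizon)
        v = traj.y[:, 0] + traj.y[:, 1]
        if np.any(np.diff(v) > 1e-9 * params.N):
            monotone = False
        v_lims.append(float(v[-1]))
        c_lims.append(float(traj.y[-1, 1]))
    return NoParoleDecline(
        monotone=monotone, v_limits=v_lims, c_limits=c_lims,
        r0=r0_3d(params).r0,
    )
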