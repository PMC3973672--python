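"""Isocline geometry and phase-portrait classification for the planar models.

The planar reduction in (C, I) of the 3-compartment model has two
isoclines: the dI/dt = 0 locus is the line I = [sigma/(rho_x+rho_c)]*C
through the origin, and the dC/dt = 0 locus, after clearing the street
denominator (N - I), is a conic.  Its intersections with the C-axis are
the roots of

    p(C) = -beta*C^2 + N*(beta - eps - delta - sigma)*C + eps*N^2,

one root at the origin when eps = 0, and one strictly negative root when
eps > 0 (the curve crosses the axis below the origin, so the crime-free
state disappears and bifurcates into a low-crime equilibrium).

Three arrangements of the isoclines classify the portrait:

* case1 — the second C-axis root is nonnegative (beta >= delta+sigma);
  the isoclines cross twice and the endemic equilibrium attracts.
* case2 — second root negative but the dC=0 curve rises less steeply at
  the origin than the line; the endemic state is globally stable.
* case3 — second root negative and the curve steeper than the line at the
  origin; equivalent to R0 < 1, and the crime-free state is globally
  stable in the nonnegative quadrant.

The no-parole system has its own dichotomy: above threshold every orbit
is absorbed into prison; below threshold there is a continuum of
crime-free states whose split between X and I depends on the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Params3D
from .thresholds import r0_3d
from .equilibria import EquilibriumSolution, numeric_equilibrium, endemic_3d

__all__ = [
    "Isoclines2D",
    "PhasePortraitClassification",
    "isoclines_2d",
    "equilibria_from_isoclines",
    "classify_planar",
    "classify_no_parole",
    "plot_phase_plane",
]

#: |root| below this multiple of N is treated as a boundary coincidence
ROOT_TOL = 1e-9


@dataclass
class Isoclines2D:
    """Descriptors of the planar isoclines of the (C, I) reduction."""

    line_slope: float           # dI/dt = 0: I = slope * C
    quad_coeffs: tuple[float, float, float]  # p(C) coefficients, highest first
    c_axis_roots: tuple[float, float]        # roots of p, sorted ascending
    i_axis_crossing: float      # I where the dC/dt = 0 curve meets C = 0

    def curve_points(self, params: Params3D, n: int = 200) -> np.ndarray:
        """Sample the dC/dt = 0 locus as I(C) by 1-D root bracketing."""
        from scipy.optimize import brentq
        p = params
        out = []
        for C in np.linspace(0.0, p.N, n):
            def g(I, C=C):
                X = p.N - C - I
                S = p.N - I
                inc = p.beta * X * C / S if S > 0 else 0.0
                return inc + p.eps * X - (p.delta + p.sigma) * C + p.rho_c * I
            lo, hi = 0.0, p.N - C
            if g(lo) * g(hi) <= 0:
                out.append((C, brentq(g, lo, hi)))
        return np.array(out) if out else np.empty((0, 2))


def isoclines_2d(params: Params3D) -> Isoclines2D:
    """Isocline descriptors of the planar system.

    With eps = 0 one C-axis root of the dC=0 conic sits at the origin and
    the other at N*(beta-delta-sigma)/beta; with eps > 0 the constant term
    eps*N^2 pushes one root negative and the curve crosses the I-axis
    below the origin (at eps*N/(eps - rho_c), negative whenever
    rho_c > eps).
    """
    p = params
    if p.release_total <= 0:
        raise ValueError("planar isoclines need a positive release rate; "
                         "use classify_no_parole for the zero-release system")
    slope = p.sigma / p.release_total
    a2 = -p.beta
    a1 = p.N * (p.beta - p.eps - p.delta - p.sigma)
    a0 = p.eps * p.N**2
    if p.beta > 0:
        roots = tuple(sorted(np.roots([a2, a1, a0]).real))
    else:
        roots = tuple(sorted([0.0, a0 / -a1 if a1 != 0 else 0.0]))
    if p.eps == 0:
        crossing = 0.0
    elif p.rho_c != p.eps:
        crossing = p.eps * p.N / (p.eps - p.rho_c)
    else:
        crossing = float("-inf")
    return Isoclines2D(
        line_slope=float(slope),
        quad_coeffs=(a2, a1, a0),
        c_axis_roots=(float(roots[0]), float(roots[1])),
        i_axis_crossing=float(crossing),
    )


def equilibria_from_isoclines(params: Params3D) -> list[tuple[float, float]]:
    """(C, I) intersections of the two isoclines in the admissible triangle.

    Substituting I = slope*C into the cleared dC/dt = 0 conic leaves a
    quadratic in C; its admissible roots are the planar equilibria.
    """
    p = params
    s = p.sigma / p.release_total
    b, eps, N = p.beta, p.eps, p.N
    a2 = -b * (1 + s) + eps * s * (1 + s) - (p.rho_c * s - p.delta - p.sigma) * s
    a1 = b * N - eps * N * (1 + 2 * s) + (p.rho_c * s - p.delta - p.sigma) * N
    a0 = eps * N * N
    roots = np.roots([a2, a1, a0]) if a2 != 0 else np.array([-a0 / a1])
    cmax = N / (1 + s)
    out = []
    for r in roots:
        if abs(r.imag) < 1e-9 and -ROOT_TOL * N <= r.real <= cmax * (1 + 1e-12):
            C = max(float(r.real), 0.0)
            out.append((C, s * C))
    return sorted(out)


@dataclass
class PhasePortraitClassification:
    """Geometric case label with supporting isoclines and equilibria."""

    case_label: str  # case1 | case2 | case3 | at | all_in_prison | multi_crime_free
    isoclines: Isoclines2D | None
    equilibria: list[EquilibriumSolution] = field(default_factory=list)
    orbit_endpoints: list[np.ndarray] = field(default_factory=list)
    orbit_agrees: bool = True
    r0: float = float("nan")


def _reference_orbit(model: str, params, init, horizon=1e5):
    from .simulate import integrate
    traj = integrate(model, params, init, horizon=horizon)
    return traj.final_state


def classify_planar(params: Params3D, check_orbit: bool = True) -> PhasePortraitClassification:
    """Classify the planar portrait into the three isocline arrangements.

    The second C-axis root of the dC=0 conic and the comparison of the two
    isocline slopes at the origin, written denominator-free as
    ``(delta+sigma-beta)*(rho_x+rho_c) vs sigma*rho_c``, decide the case;
    case3 is algebraically equivalent to R0 < 1.  A reference orbit from a
    1% perturbation of the crime-free corner is integrated and checked
    against the predicted attractor.
    """
    p = params
    iso = isoclines_2d(p)
    r0 = r0_3d(p).r0
    # the case conditions are those of the eps = 0 geometry (the eps > 0
    # portrait is the same arrangement with the conic shifted down and the
    # relevant equilibrium bifurcated); root2 = N*(beta-delta-sigma)/beta
    root2 = p.N * (p.beta - p.delta - p.sigma) / p.beta if p.beta > 0 else -p.N
    steeper = (p.delta + p.sigma - p.beta) * p.release_total - p.sigma * p.rho_c

    if abs(root2) < ROOT_TOL * p.N or (root2 < 0 and abs(steeper) < ROOT_TOL):
        label = "at"
    elif root2 >= 0:
        label = "case1"
    elif steeper < 0:
        label = "case2"
    else:
        label = "case3"

    eqs: list[EquilibriumSolution] = []
    if p.eps == 0:
        en = endemic_3d(p)
        if en is not None:
            eqs.append(en)
    else:
        eqs.append(numeric_equilibrium("3d", p))

    agrees = True
    endpoints = []
    if check_orbit and label != "at":
        init = np.array([0.99 * p.N, 0.01 * p.N, 0.0])
        final = _reference_orbit("3d", p, init)
        endpoints.append(final)
        if label == "case3":
            target = np.array([p.N, 0.0, 0.0]) if p.eps == 0 else eqs[0].state
        else:
            target = eqs[0].state
        agrees = bool(np.max(np.abs(final - target)) < 1e-3 * p.N)
    return PhasePortraitClassification(
        case_label=label, isoclines=iso, equilibria=eqs,
        orbit_endpoints=endpoints, orbit_agrees=agrees, r0=r0,
    )


def classify_no_parole(params: Params3D, n_orbits: int = 5, seed: int = 0,
                       horizon: float = 5e3) -> PhasePortraitClassification:
    """Dichotomy of the zero-release system, verified by simulation.

    R0 = beta/(delta+sigma) > 1: every orbit tends to the everyone-in-
    prison state (X, C -> 0).  R0 < 1: a continuum of crime-free states;
    orbits end with C = 0 but initial-condition-dependent splits between
    X and I.
    """
    from .simulate import integrate

    p = params
    if not p.is_no_parole or p.eps != 0:
        raise ValueError("classification requires zero release rates and eps = 0")
    r0 = r0_3d(p).r0
    rng = np.random.default_rng(seed)
    finals = []
    for _ in range(n_orbits):
        frac = rng.dirichlet(np.ones(3))
        traj = integrate("no_parole", p, frac * p.N, horizon=horizon)
        finals.append(traj.final_state)
    label = "all_in_prison" if r0 > 1 else "multi_crime_free"
    if r0 > 1:
        agrees = all(f[0] + f[1] < 1e-5 * p.N for f in finals)
    else:
        x_lims = [f[0] for f in finals]
        agrees = (
            all(f[1] < 1e-6 * p.N for f in finals)
            and (max(x_lims) - min(x_lims)) > 1e-3 * p.N
        )
    return PhasePortraitClassification(
        case_label=label, isoclines=None, equilibria=[],
        orbit_endpoints=finals, orbit_agrees=bool(agrees), r0=r0,
    )


def plot_phase_plane(params: Params3D, path: str, grid: int = 20) -> None:
    """Write a vector-field + isoclines figure (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .dynamics import rhs_raw

    p = params
    iso = isoclines_2d(p)
    fig, ax = plt.subplots(figsize=(6, 5))
    Cs = np.linspace(0, p.N, grid)
    Is = np.linspace(0, p.N, grid)
    for C in Cs:
        for I in Is:
            if C + I > p.N:
                continue
            dC, dI = rhs_raw["reduced_2d"]((C, I), p)
            n = np.hypot(dC, dI) or 1.0
            ax.quiver(C, I, dC / n, dI / n, angles="xy", scale=40, width=2e-3,
                      color="0.6")
    pts = iso.curve_points(p)
    if len(pts):
        ax.plot(pts[:, 0], pts[:, 1], "b-", label="dC/dt = 0")
    cline = np.linspace(0, p.N, 50)
    ax.plot(cline, iso.line_slope * cline, "r-", label="dI/dt = 0")
    for C, I in equilibria_from_isoclines(p):
        ax.plot(C, I, "ko", ms=7)
    ax.set_xlim(0, p.N); ax.set_ylim(0, p.N)
    ax.set_xlabel("C (criminally active)"); ax.set_ylabel("I (incarcerated)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
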