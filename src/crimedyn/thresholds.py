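"""Basic reproduction ratios (tipping points) and their parameter sensitivities.

Each model family admits a closed-form dimensionless ratio R0 — the number
of people one criminally active person recruits into crime over their
active period — written as a sum of input/output ratios, one per path from
X into an active-criminal compartment:

3D:   R0 = beta / (delta + sigma * w),  w = rho_x/(rho_x + rho_c)

5D:   R0 = beta/(delta1+sigma1)
           + beta*sigma1*nu / ((delta1+sigma1)(delta2+sigma2)*phi)

9D:   T1 = beta/(delta1+sigma1)
      T2 = T1 * sigma1*nu1 / (phi1*(delta2+sigma2) + sigma2*nu1)
      T3 = T2 * sigma2*nu2 / (phi2*(delta3+sigma3))
      R0 = T1 + T2 + T3

with nu = nu_p + nu_c (the recidivism rates enter only through their sum).
R0 is independent of the release rates (prison-term length) and of eps:
the same ratio separates the low-crime from the high-crime regime when
eps > 0.  Crossing R0 = 1 tips the long-run outcome between the
crime-free (or low-crime) and the endemic high-crime equilibrium.

Sensitivities are computed analytically from these closed forms; central
finite differences serve only as cross-checks.  The sign of dR0/dsigma1
flips at nu*delta1 = (delta2+sigma2)*phi: incarcerating more first-time
offenders reduces long-run crime only while recidivism is small relative
to rehabilitation and redemption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Params3D, Params5D, Params9D

__all__ = [
    "ThresholdReport",
    "SensitivityReport",
    "r0_3d",
    "r0_5d",
    "r0_9d",
    "condition_first_offender_benefit",
    "dr0_dsigma1",
    "sensitivity_suite",
]

#: half-width of the band reported as "at" the threshold
REGIME_BAND = 1e-9


@dataclass
class ThresholdReport:
    """R0 with its input/output term decomposition and regime call."""

    r0: float
    terms: list[tuple[str, float]]
    regime: str  # "below" | "above" | "at"
    band: float = REGIME_BAND

    def __post_init__(self):
        if self.r0 < 0:
            raise ValueError("r0 must be nonnegative")


def _report(terms: list[tuple[str, float]]) -> ThresholdReport:
    r0 = float(sum(v for _, v in terms))
    if abs(r0 - 1.0) < REGIME_BAND:
        regime = "at"
    elif r0 < 1.0:
        regime = "below"
    else:
        regime = "above"
    return ThresholdReport(r0=r0, terms=terms, regime=regime)


def r0_3d(params: Params3D) -> ThresholdReport:
    """Tipping point of the 3-compartment model, beta/(delta + sigma*w).

    The incarceration rate is attenuated by the non-recidivism release
    fraction w = rho_x/(rho_x+rho_c), because a share rho_c/(rho_x+rho_c)
    of the incarcerated return directly to crime.  Independent of eps.
    In the no-parole limit (no release at all) w = 1 and the threshold is
    beta/(delta+sigma).
    """
    denom = params.delta + params.sigma * params.nonrecidivism_fraction
    if denom <= 0:
        raise ZeroDivisionError(
            "r0_3d undefined: delta + sigma*w is zero (no exit from crime)"
        )
    return _report([("onset X->C", params.beta / denom)])


def r0_5d(params: Params5D) -> ThresholdReport:
    """Tipping point of the 5-compartment model: two input/output terms.

    First term: onset pressure beta against the exits from C1
    (delta1 + sigma1).  Second term: the recidivism loop — those
    incarcerated (sigma1), released, and recruited back (nu = nu_p+nu_c)
    against the recidivist exits (delta2 + sigma2) and redemption (phi).
    Independent of rho and eps.
    """
    d1 = params.delta1 + params.sigma1
    if d1 <= 0:
        raise ZeroDivisionError("r0_5d undefined: delta1 + sigma1 is zero")
    t1 = params.beta / d1
    nu = params.nu
    if nu == 0:
        t2 = 0.0
    else:
        d2 = (params.delta2 + params.sigma2) * params.phi
        if d2 <= 0:
            raise ZeroDivisionError(
                "r0_5d undefined: (delta2+sigma2)*phi is zero with nu > 0"
            )
        t2 = t1 * params.sigma1 * nu / d2
    return _report([("onset X->C1", t1), ("recidivism loop X->C2", t2)])


def r0_9d(params: Params9D) -> ThresholdReport:
    """Tipping point of the 9-compartment model: three input/output terms.

    T1 covers the path X->C1; T2 the path on to C2 (note the extra
    sigma2*nu1 in its denominator: a second incarceration removes the
    offender from the first reentry loop, unlike in the single-prison 5D
    model); T3 the path on to C3, whose incarceration returns to R2.
    Independent of rho1, rho2, rho3 and eps.
    """
    d1 = params.delta1 + params.sigma1
    if d1 <= 0:
        raise ZeroDivisionError("r0_9d undefined: delta1 + sigma1 is zero")
    t1 = params.beta / d1
    nu1, nu2 = params.nu1, params.nu2
    if nu1 == 0:
        t2 = t3 = 0.0
    else:
        den2 = params.phi1 * (params.delta2 + params.sigma2) + params.sigma2 * nu1
        if den2 <= 0:
            raise ZeroDivisionError(
                "r0_9d undefined: stage-2 outflow denominator is zero with nu1 > 0"
            )
        t2 = t1 * params.sigma1 * nu1 / den2
        if nu2 == 0 or t2 == 0.0:
            t3 = 0.0
        else:
            den3 = params.phi2 * (params.delta3 + params.sigma3)
            if den3 <= 0:
                raise ZeroDivisionError(
                    "r0_9d undefined: stage-3 outflow denominator is zero with nu2 > 0"
                )
            t3 = t2 * params.sigma2 * nu2 / den3
    return _report(
        [("onset X->C1", t1), ("recidivism X->C2", t2), ("recidivism X->C3", t3)]
    )


# ---------------------------------------------------------------------------
# Sensitivities (5D)
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    """Analytic partial derivative of R0 with a finite-difference check."""

    parameter: str
    analytic: float
    fd_check: float
    sign: str  # "negative" | "positive" | "zero"
    extra: dict = field(default_factory=dict)

    @property
    def agrees(self) -> bool:
        scale = max(abs(self.analytic), abs(self.fd_check), 1e-300)
        return abs(self.analytic - self.fd_check) <= 1e-6 * scale


def condition_first_offender_benefit(params: Params5D) -> bool:
    """True when incarcerating more first offenders lowers R0.

    The sign of dR0/dsigma1 is the sign of nu*delta1 - (delta2+sigma2)*phi:
    the benefit condition holds while recidivism (nu, weighted by the
    desistance rate delta1) is small relative to rehabilitation
    (delta2+sigma2) and redemption (phi).
    """
    return params.nu * params.delta1 < (params.delta2 + params.sigma2) * params.phi


def _fd(params: Params5D, name: str, rel: float = 1e-6) -> float:
    x = getattr(params, name)
    h = rel * max(abs(x), 1.0)
    hi = r0_5d(params.replace(**{name: x + h})).r0
    lo_x = x - h
    if lo_x < 0:  # one-sided at the domain boundary
        return (hi - r0_5d(params).r0) / h
    lo = r0_5d(params.replace(**{name: lo_x})).r0
    return (hi - lo) / (2 * h)


def _fd_nu(params: Params5D, rel: float = 1e-6) -> float:
    """Finite difference in the combined nu, varied through nu_p."""
    x = params.nu_p
    h = rel * max(abs(params.nu), 1.0)
    hi = r0_5d(params.replace(nu_p=x + h)).r0
    if x - h < 0:
        return (hi - r0_5d(params).r0) / h
    lo = r0_5d(params.replace(nu_p=x - h)).r0
    return (hi - lo) / (2 * h)


def _sign(v: float, tol: float = 0.0) -> str:
    if v > tol:
        return "positive"
    if v < -tol:
        return "negative"
    return "zero"


def _partials(params: Params5D) -> dict[str, float]:
    b = params.beta
    d1, s1 = params.delta1, params.sigma1
    d2, s2, phi = params.delta2, params.sigma2, params.phi
    nu = params.nu
    A = d1 + s1
    k = nu / ((d2 + s2) * phi) if nu > 0 else 0.0
    r0 = b * (1 + k * s1) / A
    return {
        "beta": (1 + k * s1) / A,
        "sigma1": b * (k * d1 - 1) / A**2,
        "delta1": -b * (1 + k * s1) / A**2,
        "sigma2": -b * s1 * nu / (A * (d2 + s2) ** 2 * phi) if nu > 0 else 0.0,
        "delta2": -b * s1 * nu / (A * (d2 + s2) ** 2 * phi) if nu > 0 else 0.0,
        "phi": -b * s1 * nu / (A * (d2 + s2) * phi**2) if nu > 0 else 0.0,
        "nu": b * s1 / (A * (d2 + s2) * phi),
        "r0": r0,
    }


def dr0_dsigma1(params: Params5D) -> SensitivityReport:
    """Effect of first-offender incarceration on the tipping point.

    Negative exactly when :func:`condition_first_offender_benefit` holds;
    when recidivism outweighs rehabilitation and redemption, pushing up
    sigma1 raises R0 — over-incarceration of first-time offenders becomes
    counter-productive.
    """
    analytic = _partials(params)["sigma1"]
    fd = _fd(params, "sigma1")
    return SensitivityReport(
        parameter="sigma1",
        analytic=analytic,
        fd_check=fd,
        sign=_sign(analytic),
        extra={"benefit_condition_holds": condition_first_offender_benefit(params)},
    )


def sensitivity_suite(params: Params5D) -> list[SensitivityReport]:
    """Partials of the 5D R0 w.r.t. sigma2, delta1, delta2, phi, beta, nu.

    Signs are structural: crime prevalence falls with recidivist
    enforcement (sigma2) and with every desistance/redemption channel
    (delta1, delta2, phi, the last strictly only when a recidivism path
    exists), and rises with the contagion rate beta and with recidivism nu.
    """
    p = _partials(params)
    reports = []
    for name in ("sigma2", "delta1", "delta2", "phi", "beta"):
        reports.append(
            SensitivityReport(
                parameter=name,
                analytic=p[name],
                fd_check=_fd(params, name),
                sign=_sign(p[name]),
            )
        )
    reports.append(
        SensitivityReport(
            parameter="nu",
            analytic=p["nu"],
            fd_check=_fd_nu(params),
            sign=_sign(p["nu"]),
        )
    )
    return reports


def fraction_desistance_dominant(param_draws) -> float:
    """Fraction of parameter sets with |dR0/ddelta1| > |dR0/dsigma1|.

    Across reasonable parameter choices this is a large majority: social
    interventions encouraging desistance of not-yet-incarcerated criminals
    move the tipping point more than first-offender enforcement does.
    """
    n_dom = 0
    draws = list(param_draws)
    for p in draws:
        parts = _partials(p)
        n_dom += abs(parts["delta1"]) > abs(parts["sigma1"])
    return n_dom / len(draws)
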