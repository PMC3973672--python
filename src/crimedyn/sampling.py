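"""Random admissible parameter sets for property tests and experiments.

Rates are drawn log-uniformly on [1e-2, 1e1], a range wide enough to put
substantial probability on both sides of the R0 = 1 tipping point and on
both sides of the first-offender benefit condition
nu*delta1 < (delta2+sigma2)*phi.  Recidivism contagion (nu_c) defaults to
zero: with nu_c > 0 the crime-free state can be locally stable even when
the global-stability threshold R0 exceeds one (the contagion term is
second order at the origin), so threshold-vs-simulation properties are
stated for the contagion-only-onset, propensity-only-recidivism models,
exactly where the closed-form prevalence law holds.
"""

from __future__ import annotations

import numpy as np

from .params import Params3D, Params5D, Params9D

__all__ = [
    "loguniform_rate",
    "sample_params_3d",
    "sample_params_5d",
    "sample_params_9d",
]

RATE_RANGE = (1e-2, 1e1)


def loguniform_rate(rng: np.random.Generator, size=None,
                    lo: float = RATE_RANGE[0], hi: float = RATE_RANGE[1]):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def sample_params_3d(rng: np.random.Generator, eps: float = 0.0,
                     N: float = 120.0) -> Params3D:
    b, d, s, rx, rc = loguniform_rate(rng, 5)
    return Params3D(beta=b, delta=d, sigma=s, rho_x=rx, rho_c=rc, eps=eps, N=N)


def sample_params_5d(rng: np.random.Generator, eps: float = 0.0,
                     include_nu_c: bool = False, N: float = 120.0) -> Params5D:
    b, d1, s1, rho, nup, d2, s2, phi = loguniform_rate(rng, 8)
    nuc = float(loguniform_rate(rng)) if include_nu_c else 0.0
    return Params5D(beta=b, eps=eps, delta1=d1, sigma1=s1, rho=rho,
                    nu_p=nup, nu_c=nuc, delta2=d2, sigma2=s2, phi=phi, N=N)


def sample_params_9d(rng: np.random.Generator, eps: float = 0.0,
                     include_nu_c: bool = False, N: float = 120.0) -> Params9D:
    v = loguniform_rate(rng, 13)
    nuc1 = float(loguniform_rate(rng)) if include_nu_c else 0.0
    nuc2 = float(loguniform_rate(rng)) if include_nu_c else 0.0
    return Params9D(
        beta=v[0], eps=eps,
        delta1=v[1], sigma1=v[2], rho1=v[3], nu_p1=v[4], nu_c1=nuc1, phi1=v[5],
        delta2=v[6], sigma2=v[7], rho2=v[8], nu_p2=v[9], nu_c2=nuc2, phi2=v[10],
        delta3=v[11], sigma3=v[12], rho3=float(loguniform_rate(rng)), N=N,
    )
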