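"""Parameter sets and state-vector conventions for the model hierarchy.

Six models are organised along two axes: the number of compartments
(3, 5 or 9) and whether onset of crime is purely contagious (``eps == 0``)
or also carries an autonomous propensity term (``eps > 0``).

========  ==========  =================================
states    contagion    contagion + propensity
========  ==========  =================================
3         Model 1      Model 2
5         Model 3      Model 4
9         Model 5      Model 6 (``rho3 == 0``: strict
                       three-strike regime)
========  ==========  =================================

All rates are per unit time; ``N`` is the (conserved) population size in
persons.  Compartment naming:

* ``X``  — not criminally active, never incarcerated (or redeemed),
* ``C``/``C1``/``C2``/``C3`` — criminally active (by incarceration spell),
* ``I``/``I1``/``I2``/``I3`` — incarcerated (by spell),
* ``R``/``R1``/``R2`` — released from prison, currently not active.

The docs ship a mapping from these semantic names to the conventional
Greek symbols (beta, delta, sigma, rho, nu, phi, epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Params3D",
    "Params5D",
    "Params9D",
    "Trajectory",
    "COMPARTMENTS",
    "state_array",
    "validate_state",
]

#: compartment names, in the fixed state ordering, per model family
COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "3d": ("X", "C", "I"),
    "reduced_2d": ("C", "I"),
    "no_parole": ("X", "C", "I"),
    "5d": ("X", "C1", "I", "R", "C2"),
    "9d": ("X", "C1", "I1", "R1", "C2", "I2", "R2", "C3", "I3"),
}


class _ParamsBase:
    """Shared validation: nonnegative rates, positive population."""

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v!r}")
        if self.N <= 0:
            raise ValueError(f"population N must be positive, got {self.N!r}")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw):
        d = self.to_dict()
        d.update(kw)
        return type(self)(**d)


@dataclass(frozen=True)
class Params3D(_ParamsBase):
    """Rates for the 3-compartment models (Models 1 and 2).

    Parameters
    ----------
    beta : contagion rate of criminal onset (per active contact share).
    delta : desistance rate C -> X.
    sigma : incarceration rate C -> I.
    rho_x : release rate I -> X (released, assimilates back into society).
    rho_c : release rate I -> C (released, returns to criminal life).
    eps : autonomous onset rate X -> C; ``0`` selects Model 1.
    N : total population.
    """

    beta: float
    delta: float
    sigma: float
    rho_x: float
    rho_c: float
    eps: float = 0.0
    N: float = 120.0

    @property
    def release_total(self) -> float:
        return self.rho_x + self.rho_c

    @property
    def nonrecidivism_fraction(self) -> float:
        """Fraction of released prisoners who assimilate, rho_x/(rho_x+rho_c).

        Equals 1 by convention when there is no release at all (the
        no-parole limit, where the threshold is beta/(delta+sigma)).
        """
        tot = self.release_total
        return self.rho_x / tot if tot > 0 else 1.0

    @property
    def is_no_parole(self) -> bool:
        return self.release_total == 0.0


@dataclass(frozen=True)
class Params5D(_ParamsBase):
    """Rates for the full 5-compartment models (Models 3 and 4).

    Parameters
    ----------
    beta : contagion onset rate X -> C1.
    eps : autonomous onset rate X -> C1 (0 selects Model 3).
    delta1 : first-offender desistance C1 -> X.
    sigma1 : first-offender incarceration C1 -> I.
    rho : release rate I -> R; 1/rho is the mean prison-term length.
    nu_p : recidivism propensity R -> C2.
    nu_c : recidivism contagion coefficient R -> C2.
    delta2 : recidivist desistance C2 -> R.
    sigma2 : re-incarceration C2 -> I.
    phi : redemption rate R -> X.
    N : total population.
    """

    beta: float
    eps: float
    delta1: float
    sigma1: float
    rho: float
    nu_p: float
    nu_c: float
    delta2: float
    sigma2: float
    phi: float
    N: float = 120.0

    @property
    def nu(self) -> float:
        """Combined recidivism onset; enters R0 only through this sum."""
        return self.nu_p + self.nu_c


@dataclass(frozen=True)
class Params9D(_ParamsBase):
    """Rates for the 9-compartment three-strike models (Models 5 and 6).

    Stage ``k`` (1, 2, 3) refers to the k-th incarceration spell, reentry
    stage ``j`` (1, 2) to the return from the j-th spell.  ``rho3 == 0``
    is the strict three-strike regime (mandatory life after the third
    conviction, I3 absorbing); ``rho3 > 0`` allows leakage.
    """

    beta: float
    eps: float
    delta1: float
    sigma1: float
    rho1: float
    nu_p1: float
    nu_c1: float
    phi1: float
    delta2: float
    sigma2: float
    rho2: float
    nu_p2: float
    nu_c2: float
    phi2: float
    delta3: float
    sigma3: float
    rho3: float
    N: float = 120.0

    @property
    def nu1(self) -> float:
        return self.nu_p1 + self.nu_c1

    @property
    def nu2(self) -> float:
        return self.nu_p2 + self.nu_c2

    @property
    def is_three_strike(self) -> bool:
        return self.rho3 == 0.0


def state_array(model: str, state: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Coerce a state given as mapping or sequence into the fixed ordering."""
    names = COMPARTMENTS[model]
    if isinstance(state, Mapping):
        missing = set(names) - set(state)
        if missing:
            raise ValueError(f"state missing compartments {sorted(missing)}")
        arr = np.array([float(state[k]) for k in names])
    else:
        arr = np.asarray(state, dtype=float)
        if arr.shape != (len(names),):
            raise ValueError(
                f"model {model!r} expects {len(names)} compartments {names}, "
                f"got shape {arr.shape}"
            )
    return arr


def validate_state(model: str, state: np.ndarray, N: float | None = None,
                   tol: float = 1e-9) -> None:
    """Reject negative occupancies; optionally check conservation to ``tol*N``."""
    if np.any(state < 0):
        raise ValueError(f"negative compartment occupancy: {state}")
    if N is not None and model != "reduced_2d":
        if abs(float(np.sum(state)) - N) > tol * N:
            raise ValueError(
                f"state sums to {np.sum(state)!r}, expected N={N!r}"
            )


@dataclass
class Trajectory:
    """Integrated orbit: time grid, state matrix (rows = times), provenance."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_compartments)
    model: str
    params: object

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != self.t.shape[0]:
            raise ValueError("time grid and state matrix lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    @property
    def compartments(self) -> tuple[str, ...]:
        return COMPARTMENTS[self.model]
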