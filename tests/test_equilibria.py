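"""Endemic equilibria: residuals, the 1/R0 prevalence law, numeric solver."""

import numpy as np
import pytest

import crimedyn as cd
from crimedyn.dynamics import rhs_raw
from crimedyn.sampling import sample_params_3d, sample_params_5d, sample_params_9d

N = 120.0

_SAMPLERS = {"3d": sample_params_3d, "5d": sample_params_5d, "9d": sample_params_9d}
_CLOSED = {"3d": cd.endemic_3d, "5d": cd.endemic_5d, "9d": cd.endemic_9d}
_R0 = {"3d": cd.r0_3d, "5d": cd.r0_5d, "9d": cd.r0_9d}


@pytest.mark.parametrize("model", ["3d", "5d", "9d"])
def test_closed_form_residual_and_prevalence_law(model, rng):
    """Plugging the closed form into the RHS leaves residual < 1e-10 N, and
    the street non-criminal fraction equals 1/r0 to 1e-10."""
    n_endemic = 0
    for _ in range(60):
        p = _SAMPLERS[model](rng)
        eq = _CLOSED[model](p)
        r0 = _R0[model](p).r0
        if r0 <= 1:
            assert eq is None
            continue
        n_endemic += 1
        assert eq.residual < 1e-10 * N
        assert eq.street_noncriminal_prevalence == pytest.approx(1 / r0, abs=1e-10)
        assert np.all(eq.state >= 0) and eq.state.sum() == pytest.approx(N, rel=1e-12)
    assert n_endemic >= 10


def test_prevalence_at_exact_r0_values():
    """r0 = 2 gives street split 50/50 (3D and 5D); r0 = 4 gives 25/75 (9D)."""
    p3 = cd.Params3D(beta=1.5, delta=0.5, sigma=0.5, rho_x=1.0, rho_c=1.0)
    assert cd.r0_3d(p3).r0 == pytest.approx(2.0, rel=1e-12)
    assert cd.endemic_3d(p3).street_noncriminal_prevalence == pytest.approx(0.5, abs=1e-12)

    p5 = cd.Params5D(beta=1.0, eps=0.0, delta1=0.5, sigma1=0.5, rho=0.5,
                     nu_p=0.7, nu_c=0.0, delta2=0.3, sigma2=0.4, phi=0.5)
    r5 = cd.r0_5d(p5).r0
    scale = 2.0 / r5
    p5 = p5.replace(beta=scale)  # r0 scales linearly in beta
    assert cd.r0_5d(p5).r0 == pytest.approx(2.0, rel=1e-12)
    eq = cd.endemic_5d(p5)
    street = eq.state[0] + eq.state[1] + eq.state[3] + eq.state[4]
    assert eq.state[0] / street == pytest.approx(0.5, abs=1e-12)

    p9 = cd.Params9D(beta=1.0, eps=0.0,
                     delta1=0.3, sigma1=0.4, rho1=0.5, nu_p1=0.4, nu_c1=0.0, phi1=0.3,
                     delta2=0.25, sigma2=0.5, rho2=0.4, nu_p2=0.5, nu_c2=0.0, phi2=0.35,
                     delta3=0.2, sigma3=0.6, rho3=0.3)
    p9 = p9.replace(beta=4.0 / cd.r0_9d(p9).r0 * p9.beta)
    assert cd.r0_9d(p9).r0 == pytest.approx(4.0, rel=1e-12)
    assert cd.endemic_9d(p9).street_noncriminal_prevalence == pytest.approx(0.25, abs=1e-12)


def test_below_threshold_returns_none(p3_sub):
    assert cd.endemic_3d(p3_sub) is None
    p5 = cd.Params5D(beta=0.2, eps=0.0, delta1=0.5, sigma1=0.5, rho=0.5,
                     nu_p=0.1, nu_c=0.0, delta2=0.5, sigma2=0.5, phi=1.0)
    assert cd.r0_5d(p5).r0 < 1 and cd.endemic_5d(p5) is None


def test_no_recidivism_collapses_to_3d_form(p5_base):
    eq = cd.endemic_5d(p5_base.replace(nu_p=0.0))
    assert eq.state[4] == 0.0  # C2 empty
    p9_no_recid = cd.Params9D(beta=1.2, eps=0.0,
                              delta1=0.3, sigma1=0.4, rho1=0.5, nu_p1=0.0, nu_c1=0.0,
                              phi1=0.3, delta2=0.25, sigma2=0.5, rho2=0.4, nu_p2=0.0,
                              nu_c2=0.0, phi2=0.35, delta3=0.2, sigma3=0.6, rho3=0.3)
    eq9 = cd.endemic_9d(p9_no_recid)
    assert np.all(eq9.state[4:] == 0.0)  # stages 2-3 empty


def test_guard_rails(p5_base):
    with pytest.raises(ValueError):
        cd.endemic_3d(cd.Params3D(beta=2, delta=.5, sigma=.5, rho_x=1, rho_c=.5, eps=0.1))
    with pytest.raises(ValueError):
        cd.endemic_5d(p5_base.replace(nu_c=0.5))
    with pytest.raises(ValueError):
        cd.endemic_5d(p5_base.replace(eps=0.1))


class TestNumericEquilibrium:
    def test_matches_closed_form_when_exact(self, rng):
        found = 0
        while found < 8:
            p = sample_params_5d(rng)
            eq = cd.endemic_5d(p)
            if eq is None:
                continue
            num = cd.numeric_equilibrium("5d", p)
            assert np.max(np.abs(num.state - eq.state)) < 1e-8 * max(1.0, np.max(eq.state))
            found += 1

    def test_eps_limit_approaches_crime_free_below_threshold(self, p3_sub):
        for model, p in [("3d", p3_sub),
                         ("5d", cd.Params5D(beta=0.2, eps=0.0, delta1=0.5, sigma1=0.5,
                                            rho=0.5, nu_p=0.1, nu_c=0.0, delta2=0.5,
                                            sigma2=0.5, phi=1.0))]:
            dist = []
            for eps in (1e-3, 1e-5):
                eq = cd.numeric_equilibrium(model, p.replace(eps=eps))
                assert eq.kind == "low_crime"
                crime_free = np.zeros(len(eq.state)); crime_free[0] = N
                dist.append(np.max(np.abs(eq.state - crime_free)))
            assert dist[1] < dist[0] and dist[1] < 1e-2 * N

    def test_eps_keeps_criminal_compartments_positive(self, p5_base):
        eq = cd.numeric_equilibrium("5d", p5_base.replace(eps=1e-3))
        assert eq.kind == "high_crime"
        assert np.all(eq.state[[1, 4]] > 0)
        low = cd.numeric_equilibrium("5d", p5_base.replace(beta=0.1, nu_p=0.05, eps=1e-3))
        assert low.kind == "low_crime" and np.all(low.state[[1, 4]] > 0)

    @pytest.mark.parametrize("model,eps", [("3d", 0.02), ("5d", 0.02), ("9d", 0.02)])
    def test_unique_from_dispersed_starts(self, model, eps, rng):
        """Root-finding from >= 10 dispersed starts returns one equilibrium."""
        for _ in range(4):
            p = _SAMPLERS[model](rng, eps=eps)
            states = [cd.numeric_equilibrium(model, p, n_starts=10, seed=s).state
                      for s in range(3)]
            for s in states[1:]:
                assert np.max(np.abs(s - states[0])) < 1e-6 * max(1.0, np.max(states[0]))

    def test_nine_d_numeric_residual(self, p9_base):
        eq = cd.numeric_equilibrium("9d", p9_base.replace(eps=1e-3))
        assert eq.residual < 1e-8 * N


def test_prevalence_law_fails_with_recidivism_contagion(p5_base):
    """With nu_c > 0 the street non-criminal fraction at equilibrium is NOT
    1/r0 (the identity is special to propensity-only recidivism)."""
    p = p5_base.replace(nu_c=1.5, nu_p=0.3)
    eq = cd.numeric_equilibrium("5d", p)
    assert eq.residual < 1e-8 * N
    r0 = cd.r0_5d(p).r0
    assert abs(eq.street_noncriminal_prevalence - 1 / r0) > 1e-3


def test_release_rate_moves_compartments_not_prevalence(p5_base):
    """Across two decades of rho the prevalence and r0 are unchanged while
    the individual equilibrium values move."""
    rhos = [5.0, 0.5, 0.05]
    eqs = [cd.endemic_5d(p5_base.replace(rho=r)) for r in rhos]
    prevs = [e.street_noncriminal_prevalence for e in eqs]
    assert np.ptp(prevs) < 1e-12
    I_vals = [e.state[2] for e in eqs]
    assert I_vals[0] < I_vals[1] < I_vals[2]
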