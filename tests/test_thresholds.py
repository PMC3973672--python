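"""Tipping-point formulas, their decompositions and sensitivities."""

import numpy as np
import pytest

import crimedyn as cd
from crimedyn.sampling import sample_params_3d, sample_params_5d, sample_params_9d
from crimedyn.thresholds import fraction_desistance_dominant

N = 120.0


class TestR03D:
    def test_no_contagion_no_reproduction(self):
        p = cd.Params3D(beta=0.0, delta=0.5, sigma=0.5, rho_x=1.0, rho_c=0.5)
        assert cd.r0_3d(p).r0 == 0.0

    def test_zero_recidivism_release_threshold_at_beta_equals_exits(self):
        """With rho_c = 0 the non-recidivism factor is 1, so
        beta = delta + sigma sits exactly on the threshold; a simulated
        regime flip brackets the same point."""
        base = dict(delta=0.5, sigma=0.5, rho_x=1.0, rho_c=0.0)
        rep = cd.r0_3d(cd.Params3D(beta=1.0, **base))
        assert rep.r0 == pytest.approx(1.0, abs=1e-12)
        assert rep.regime == "at"
        for beta, goes_crime_free in [(0.8, True), (1.25, False)]:
            p = cd.Params3D(beta=beta, **base)
            traj = cd.integrate("3d", p, cd.default_init("3d", p), horizon=1e5)
            assert (traj.final_state[1] < 1e-3 * N) == goes_crime_free

    def test_no_incarceration_reduces_to_sis_ratio(self):
        """With sigma = 0, r0 = beta/delta; the endemic street criminal
        prevalence from a long run equals 1 - 1/r0."""
        p = cd.Params3D(beta=1.0, delta=0.5, sigma=0.0, rho_x=1.0, rho_c=0.5)
        assert cd.r0_3d(p).r0 == pytest.approx(2.0, rel=1e-12)
        traj = cd.integrate("3d", p, cd.default_init("3d", p), horizon=1e5)
        X, C, I = traj.final_state
        assert C / (X + C) == pytest.approx(1 - 0.5, abs=1e-6)

    def test_independent_of_eps_and_release_scale(self, p3_super):
        assert cd.r0_3d(p3_super.replace(eps=0.5)).r0 == cd.r0_3d(p3_super).r0
        with pytest.raises(ZeroDivisionError):
            cd.r0_3d(cd.Params3D(beta=1, delta=0, sigma=0, rho_x=1, rho_c=1))


class TestR05D:
    def test_reduces_to_first_offender_loop_without_recidivism(self, p5_base):
        p = p5_base.replace(nu_p=0.0, nu_c=0.0)
        rep = cd.r0_5d(p)
        assert rep.r0 == pytest.approx(p.beta / (p.delta1 + p.sigma1), rel=1e-14)
        assert rep.terms[1][1] == 0.0

    def test_symmetric_in_recidivism_split(self, p5_base):
        a = cd.r0_5d(p5_base.replace(nu_p=0.7, nu_c=0.2)).r0
        b = cd.r0_5d(p5_base.replace(nu_p=0.2, nu_c=0.7)).r0
        assert a == pytest.approx(b, rel=1e-14)

    def test_independent_of_release_rate_and_eps(self, p5_base):
        r = cd.r0_5d(p5_base).r0
        assert cd.r0_5d(p5_base.replace(rho=2 * p5_base.rho)).r0 == r
        assert cd.r0_5d(p5_base.replace(eps=0.3)).r0 == r

    def test_terms_sum_and_scaling_in_beta(self, p5_base):
        rep = cd.r0_5d(p5_base)
        assert rep.r0 == pytest.approx(sum(v for _, v in rep.terms), rel=1e-14)
        doubled = cd.r0_5d(p5_base.replace(beta=2 * p5_base.beta))
        assert doubled.terms[0][1] == pytest.approx(2 * rep.terms[0][1], rel=1e-14)

    def test_zero_denominator_rejected(self, p5_base):
        with pytest.raises(ZeroDivisionError):
            cd.r0_5d(p5_base.replace(phi=0.0))


class TestR09D:
    def test_recidivism_paths_zeroed_leaves_first_term(self, p9_base):
        p = p9_base.replace(nu_p1=0.0, nu_c1=0.0)
        rep = cd.r0_9d(p)
        assert rep.r0 == pytest.approx(p.beta / (p.delta1 + p.sigma1), rel=1e-14)
        assert rep.terms[1][1] == rep.terms[2][1] == 0.0
        p2 = p9_base.replace(nu_p2=0.0, nu_c2=0.0)
        assert cd.r0_9d(p2).terms[2][1] == 0.0

    def test_depends_on_nu_pairs_only_through_sums(self, p9_base):
        a = cd.r0_9d(p9_base.replace(nu_p1=0.1, nu_c1=0.3, nu_p2=0.4, nu_c2=0.1)).r0
        b = cd.r0_9d(p9_base.replace(nu_p1=0.4, nu_c1=0.0, nu_p2=0.0, nu_c2=0.5)).r0
        assert a == pytest.approx(b, rel=1e-14)

    def test_independent_of_all_release_rates(self, p9_base):
        r = cd.r0_9d(p9_base).r0
        for name in ("rho1", "rho2", "rho3"):
            assert cd.r0_9d(p9_base.replace(**{name: 5.0})).r0 == r
        assert cd.r0_9d(p9_base.replace(rho3=0.0)).r0 == r


class TestSensitivities:
    def test_first_offender_enforcement_sign_flips_with_recidivism(self, p5_base):
        """dR0/dsigma1 < 0 while nu*delta1 < (delta2+sigma2)*phi, > 0 once
        recidivism dominates rehabilitation and redemption."""
        benign = p5_base.replace(nu_p=0.01, phi=1.0)  # condition holds
        rep = cd.dr0_dsigma1(benign)
        assert rep.extra["benefit_condition_holds"]
        assert rep.sign == "negative" and rep.agrees
        harsh = p5_base.replace(nu_p=5.0, phi=0.05, delta2=0.05, sigma2=0.05)
        rep = cd.dr0_dsigma1(harsh)
        assert not rep.extra["benefit_condition_holds"]
        assert rep.sign == "positive" and rep.agrees

    def test_analytic_matches_finite_difference(self, rng):
        for _ in range(20):
            p = sample_params_5d(rng, include_nu_c=True)
            rep = cd.dr0_dsigma1(p)
            assert rep.agrees
            for s in cd.sensitivity_suite(p):
                assert s.agrees, s

    def test_suite_signs(self, rng):
        """sigma2, delta1, delta2, phi partials negative; beta positive."""
        for _ in range(20):
            p = sample_params_5d(rng, include_nu_c=True)
            signs = {s.parameter: s.sign for s in cd.sensitivity_suite(p)}
            assert signs["sigma2"] == "negative"
            assert signs["delta1"] == "negative"
            assert signs["delta2"] == "negative"
            assert signs["phi"] == "negative"
            assert signs["beta"] == "positive"
            assert signs["nu"] == "positive"

    def test_redemption_partial_vanishes_without_recidivism(self, p5_base):
        p = p5_base.replace(nu_p=0.0, nu_c=0.0)
        signs = {s.parameter: s.analytic for s in cd.sensitivity_suite(p)}
        assert signs["phi"] == 0.0

    def test_desistance_usually_dominates_enforcement(self, rng):
        """|dR0/ddelta1| > |dR0/dsigma1| for a large majority of draws."""
        draws = [sample_params_5d(rng, include_nu_c=True) for _ in range(300)]
        frac = fraction_desistance_dominant(draws)
        assert frac > 2 / 3


@pytest.mark.parametrize("model", ["3d", "5d", "9d"])
def test_threshold_predicts_simulated_regime(model, rng):
    """Contagion-only random draws (away from r0 = 1): long-run outcome
    from a 1% perturbation is crime-free iff r0 < 1, endemic iff r0 > 1."""
    sampler = {"3d": sample_params_3d, "5d": sample_params_5d, "9d": sample_params_9d}
    r0_fn = {"3d": cd.r0_3d, "5d": cd.r0_5d, "9d": cd.r0_9d}[model]
    crim = {"3d": [1], "5d": [1, 4], "9d": [1, 4, 7]}[model]
    checked = 0
    while checked < 30:
        p = sampler[model](rng)
        r0 = r0_fn(p).r0
        if abs(r0 - 1) < 0.05:
            continue
        traj = cd.integrate(model, p, cd.default_init(model, p), horizon=1e6)
        final = traj.final_state
        crime_free = sum(final[i] for i in crim) < 1e-3 * N
        assert crime_free == (r0 < 1), (model, r0, final)
        if r0 > 1:
            eq = {"3d": cd.endemic_3d, "5d": cd.endemic_5d, "9d": cd.endemic_9d}[model](p)
            assert np.max(np.abs(final - eq.state)) < 1e-3 * N
        checked += 1


def test_same_threshold_separates_low_from_high_crime_with_eps(rng):
    """For eps > 0 the crime-free state bifurcates to a low-crime state, but
    the same r0 still separates low-crime from high-crime convergence."""
    checked = 0
    while checked < 10:
        p = sample_params_3d(rng, eps=1e-3)
        r0 = cd.r0_3d(p).r0
        if abs(r0 - 1) < 0.1:
            continue
        traj = cd.integrate("3d", p, cd.default_init("3d", p), horizon=1e6)
        eq = cd.numeric_equilibrium("3d", p)
        assert eq.kind == ("low_crime" if r0 < 1 else "high_crime")
        assert np.max(np.abs(traj.final_state - eq.state)) < 1e-3 * N
        checked += 1
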