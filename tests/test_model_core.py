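"""Unit and property tests of the structural model: body-size metrics,
maturation, GST covariate, the GSH-depletion ODE and the residual model."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import helpers
from busulfanpk import model_core as mc


class TestBodySize:
    def test_ffm_reference_adult(self):
        # 70 kg / 176 cm male standard subject
        assert mc.compute_ffm(70, 176, "male") == pytest.approx(56.13, abs=0.05)

    def test_ffm_typical_child(self):
        # matches the typical patient's tabulated fat-free mass (8.8 kg)
        assert mc.compute_ffm(9.9, 76, "male") == pytest.approx(8.84, abs=0.01)

    def test_ffm_vanishes_with_weight(self):
        assert mc.compute_ffm(1e-6, 76, "male") == pytest.approx(0.0, abs=1e-5)

    def test_ffm_bounded_by_weight(self):
        # adult-derived equation is clamped for underweight children
        ffm = mc.compute_ffm(5.0, 90.0, "male")
        assert 0 < ffm <= 5.0

    @pytest.mark.parametrize("wt,ht", [(0, 76), (9.9, 0), (-1, 76)])
    def test_ffm_invalid_inputs(self, wt, ht):
        with pytest.raises(ValueError):
            mc.compute_ffm(wt, ht, "male")

    @pytest.mark.parametrize("ffm,wt,ffat,expected", [
        (8.8, 9.9, 0.0, 8.8),        # Ffat=0 collapses NFM to FFM
        (8.8, 9.9, 1.0, 9.9),        # Ffat=1 collapses NFM to WT
        (8.8, 9.9, 0.905, 9.7955),
    ])
    def test_nfm(self, ffm, wt, ffat, expected):
        assert mc.compute_nfm(ffm, wt, ffat) == pytest.approx(expected)

    def test_nfm_invalid(self):
        with pytest.raises(ValueError):
            mc.compute_nfm(10.0, 9.9, 0.5)


class TestMaturation:
    def test_half_maximum_at_tm50(self):
        assert mc.maturation_fraction(45, 45, 1.11) == pytest.approx(0.5)

    def test_adult_asymptote(self):
        assert mc.maturation_fraction(1e7, 45, 1.11) == pytest.approx(1.0, abs=1e-4)

    def test_typical_patient_value(self):
        # PMA of the 1.4-y-old typical patient: 38.3 + 1.4*52.1775 wk
        pma = 38.3 + 1.4 * mc.WEEKS_PER_YEAR
        assert mc.maturation_fraction(pma, 45, 1.11) == pytest.approx(0.732, abs=1e-3)

    @given(st.floats(1.0, 500.0), st.floats(2.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing(self, pma, pma2):
        lo, hi = sorted([pma, pma2])
        if hi - lo < 1e-6:
            return
        assert mc.maturation_fraction(hi, 45, 1.11) > \
            mc.maturation_fraction(lo, 45, 1.11)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mc.maturation_fraction(-1, 45, 1.11)


class TestGstMultiplier:
    def test_reference_activity(self):
        assert mc.gst_multiplier(9.2, 0.28, 9.2) == pytest.approx(1.0)

    def test_zero_slope(self):
        assert mc.gst_multiplier(17.3, 0.0, 9.2) == pytest.approx(1.0)

    def test_cohort_maximum(self):
        assert mc.gst_multiplier(20.7, 0.28, 9.2) == pytest.approx(1.419, abs=1e-3)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            mc.gst_multiplier(9.2, 0.28, 0.0)


class TestIndividualParameters:
    def test_typical_patient_clearance(self, pop, typical):
        # chain: 9.57 * (9.7955/68.68)^0.75 * Fmat(111.3 wk) = 1.626 L/h
        ind = mc.individual_parameters(pop, typical)
        assert ind.cl == pytest.approx(1.626, rel=2e-3)
        assert ind.s_gsh == pytest.approx(
            pop.s_gsh * mc.gst_multiplier(10.12, 0.28, 9.2), rel=1e-9)

    def test_standard_adult_is_reference(self, pop):
        adult = mc.SubjectCovariates(id="std", sex="male", postnatal_age=30.0,
                                     gestational_age=40.0, wt=70.0, ht=176.0)
        ind = mc.individual_parameters(pop, adult)
        fmat = mc.maturation_fraction(adult.pma, pop.tm50, pop.hill)
        assert fmat > 0.98
        assert ind.cl == pytest.approx(pop.theta_cl * fmat, rel=1e-9)
        assert ind.vc == pytest.approx(pop.theta_vc, rel=1e-9)

    def test_lognormal_eta_shift(self, pop, typical):
        base = mc.individual_parameters(pop, typical)
        shifted = mc.individual_parameters(pop, typical, eta=(0.25, 0.0, 0.0))
        assert shifted.cl == pytest.approx(base.cl * np.exp(0.25), rel=1e-12)

    def test_zero_effects_fixed_point(self, pop, typical):
        a = mc.individual_parameters(pop, typical)
        b = mc.individual_parameters(pop, typical, eta=(0, 0, 0), kappa_occ=0.0)
        assert (a.cl, a.vc, a.q, a.vp) == (b.cl, b.vc, b.q, b.vp)


class TestOdeRightHandSide:
    def test_equilibrium(self, typical_individual):
        state = np.array([0.0, 0.0, 1.0, 0.0])
        d = mc.pk_rhs(0.0, state, typical_individual, 0.0, 0.1)
        assert np.allclose(d, 0.0)

    def test_mass_conservation_without_elimination(self, pop, typical):
        ind = mc.IndividualParameters(cl=1e-12, vc=4.0, q=2.0, vp=2.5,
                                      s_gsh=0.0)
        state = np.array([3.0, 1.0, 1.0, 0.0])
        d = mc.pk_rhs(0.0, state, ind, 5.0, 0.1)
        assert d[0] + d[1] == pytest.approx(5.0, abs=1e-9)

    def test_depletion_switch_off(self, typical_individual):
        ind = mc.IndividualParameters(
            cl=typical_individual.cl, vc=typical_individual.vc,
            q=typical_individual.q, vp=typical_individual.vp, s_gsh=0.0)
        state = np.array([5.0, 1.0, 0.7, 0.0])
        d = mc.pk_rhs(0.0, state, ind, 0.0, 0.1)
        assert d[2] == pytest.approx(0.1 * (1 - 0.7))


class TestSimulation:
    def test_linear_limit_matches_superposition(self, pop, typical,
                                                study_regimen_16):
        """With s_gsh = 0 the integrator must agree with the exact
        matrix-exponential solution of the linear model to 1e-4."""
        ind0 = mc.individual_parameters(pop, typical)
        ind = mc.IndividualParameters(cl=ind0.cl, vc=ind0.vc, q=ind0.q,
                                      vp=ind0.vp, s_gsh=0.0)
        obs = [1.0, 2.0, 5.5, 24.0, 47.5, 66.0, 68.0, 92.0, 110.0]
        prof = mc.simulate_profile(ind, study_regimen_16, obs, k_gsh=0.1)
        doses = [(d.start_time, d.amount, d.infusion_duration)
                 for d in study_regimen_16]
        ref_conc, _ = helpers.linear_two_compartment(
            ind.cl, ind.vc, ind.q, ind.vp, doses, obs)
        np.testing.assert_allclose(prof.conc, ref_conc, rtol=1e-4)

    def test_linear_limit_cauc_is_dose_over_clearance(self, pop, typical,
                                                      study_regimen_16):
        ind0 = mc.individual_parameters(pop, typical)
        ind = mc.IndividualParameters(cl=ind0.cl, vc=ind0.vc, q=ind0.q,
                                      vp=ind0.vp, s_gsh=0.0)
        prof = mc.simulate_profile(ind, study_regimen_16, [2.0], k_gsh=0.1,
                                   horizon=92.0 + 400.0)
        total = sum(d.amount for d in study_regimen_16)
        assert prof.cauc == pytest.approx(total / ind.cl, rel=1e-3)

    def test_single_infusion_auc_identity(self, typical_individual):
        ind0 = typical_individual
        ind = mc.IndividualParameters(cl=ind0.cl, vc=ind0.vc, q=ind0.q,
                                      vp=ind0.vp, s_gsh=0.0)
        prof = mc.simulate_profile(ind, [mc.DosingEvent(0.0, 10.0, 2.0)],
                                   [2.0], k_gsh=0.1, horizon=500.0)
        assert prof.cauc == pytest.approx(10.0 / ind.cl, rel=1e-3)

    def test_dose_proportionality(self, pop, typical):
        ind0 = mc.individual_parameters(pop, typical)
        lin = mc.IndividualParameters(cl=ind0.cl, vc=ind0.vc, q=ind0.q,
                                      vp=ind0.vp, s_gsh=0.0)
        obs = [2.0, 8.0, 20.0]
        reg1 = [mc.DosingEvent(6.0 * k, 9.9, 2.0) for k in range(4)]
        reg2 = [mc.DosingEvent(6.0 * k, 19.8, 2.0) for k in range(4)]
        p1 = mc.simulate_profile(lin, reg1, obs, k_gsh=0.1)
        p2 = mc.simulate_profile(lin, reg2, obs, k_gsh=0.1)
        np.testing.assert_allclose(p2.conc, 2.0 * p1.conc, rtol=1e-9)
        # with depletion, exposure grows super-proportionally
        d1 = mc.simulate_profile(ind0, reg1, obs, k_gsh=0.1)
        d2 = mc.simulate_profile(ind0, reg2, obs, k_gsh=0.1)
        assert d2.cauc / d1.cauc > 2.0

    def test_gsh_pool_bounds_and_washout(self, pop, typical,
                                         study_regimen_16):
        ind = mc.individual_parameters(pop, typical)
        prof = mc.simulate_profile(ind, study_regimen_16, [92.0], k_gsh=0.1)
        assert np.all(prof.gsh > 0.0)
        assert np.all(prof.gsh <= 1.0 + 1e-12)
        assert prof.gsh.min() < 1.0          # drug depletes the pool
        assert prof.gsh[-1] > 0.999          # pool recovers after washout

    def test_depletion_raises_exposure(self, pop, typical, study_regimen_16):
        ind0 = mc.individual_parameters(pop, typical)
        lin = mc.IndividualParameters(cl=ind0.cl, vc=ind0.vc, q=ind0.q,
                                      vp=ind0.vp, s_gsh=0.0)
        with_dep = mc.simulate_profile(ind0, study_regimen_16, [2.0], k_gsh=0.1)
        without = mc.simulate_profile(lin, study_regimen_16, [2.0], k_gsh=0.1)
        assert with_dep.cauc > without.cauc

    def test_exposure_monotone_in_parameters(self, pop, typical,
                                             study_regimen_16):
        """cAUC decreases with CL and increases with s_gsh over a grid."""
        ind0 = mc.individual_parameters(pop, typical)
        caucs_cl = []
        for mult in (0.6, 0.9, 1.3, 1.8):
            ind = mc.IndividualParameters(
                cl=ind0.cl * mult, vc=ind0.vc, q=ind0.q, vp=ind0.vp,
                s_gsh=ind0.s_gsh)
            caucs_cl.append(mc.simulate_profile(
                ind, study_regimen_16, [2.0], k_gsh=0.1).cauc)
        assert np.all(np.diff(caucs_cl) < 0)
        caucs_s = []
        for s in (0.0, 0.002, 0.004, 0.008):
            ind = mc.IndividualParameters(
                cl=ind0.cl, vc=ind0.vc, q=ind0.q, vp=ind0.vp, s_gsh=s)
            caucs_s.append(mc.simulate_profile(
                ind, study_regimen_16, [2.0], k_gsh=0.1).cauc)
        assert np.all(np.diff(caucs_s) > 0)

    def test_kernel_agrees_with_scipy_integrator(self, pop, typical):
        """Dual-route check of the full nonlinear system against an
        independent adaptive integrator (solve_ivp on pk_rhs)."""
        ind = mc.individual_parameters(pop, typical)
        doses = [mc.DosingEvent(6.0 * k, 11.88, 2.0) for k in range(3)]
        obs = [1.0, 2.0, 4.0, 6.0, 12.0, 14.0, 20.0]
        prof = mc.simulate_profile(ind, doses, obs, k_gsh=pop.k_gsh,
                                   horizon=20.0, dt=0.05)

        def rate(t):
            for d in doses:
                if d.start_time <= t < d.start_time + d.infusion_duration:
                    return d.amount / d.infusion_duration
            return 0.0

        y = np.array([0.0, 0.0, 1.0, 0.0])
        t0 = 0.0
        conc = {}
        knots = sorted({d.start_time for d in doses}
                       | {d.start_time + d.infusion_duration for d in doses}
                       | set(obs) | {20.0})
        for t1 in knots:
            if t1 <= t0:
                continue
            r = rate(0.5 * (t0 + t1))
            sol = solve_ivp(lambda t, s: mc.pk_rhs(t, s, ind, r, pop.k_gsh),
                            (t0, t1), y, rtol=1e-10, atol=1e-12)
            y = sol.y[:, -1]
            conc[t1] = y[0] / ind.vc
            t0 = t1
        ref = np.array([conc[t] for t in obs])
        np.testing.assert_allclose(prof.conc, ref, rtol=1e-5, atol=1e-9)


class TestResidualModel:
    def test_no_noise(self, rng):
        assert mc.apply_residual(1.23, 0.0, 0.0, rng) == 1.23

    def test_zero_concentration_additive_only(self, rng):
        y = mc.apply_residual(np.zeros(50000), 0.111, 0.0166, rng)
        assert np.std(y) == pytest.approx(0.0166, rel=0.02)

    def test_combined_variance(self, rng):
        y = mc.apply_residual(np.ones(100000), 0.111, 0.0166, rng)
        expected_sd = np.sqrt(0.111 ** 2 + 0.0166 ** 2)   # 0.1122
        assert np.mean(y) == pytest.approx(1.0, abs=2e-3)
        assert np.std(y) == pytest.approx(expected_sd, abs=2e-3)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            mc.apply_residual(1.0, -0.1, 0.0, rng)


class TestInvariantsOfTypes:
    def test_subject_requires_positive_weight(self):
        with pytest.raises(ValueError):
            mc.SubjectCovariates(id="x", wt=-1, ffm=1.0)

    def test_subject_ffm_from_height(self):
        s = mc.SubjectCovariates(id="x", wt=9.9, ht=76.0, sex="male")
        assert s.ffm == pytest.approx(8.84, abs=0.01)

    def test_pma_composition(self):
        s = mc.SubjectCovariates(id="x", wt=9.9, ffm=8.8,
                                 postnatal_age=1.4, gestational_age=38.3)
        assert s.pma == pytest.approx(38.3 + 1.4 * 52.1775)

    def test_population_parameter_validation(self):
        with pytest.raises(ValueError):
            mc.PopulationParameters(theta_cl=-1.0)

    def test_dosing_event_validation(self):
        with pytest.raises(ValueError):
            mc.DosingEvent(0.0, 5.0, 0.0)
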