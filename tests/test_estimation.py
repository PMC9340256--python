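"""Estimation engine: oracle equivalences, conditional etas, fitting."""

import numpy as np
import pytest
from scipy import integrate

import escipk.estimation as est
from escipk.estimation import (
    FitConfig,
    FoceEngine,
    Observation,
    PKDataset,
    SubjectRecord,
    conditional_eta,
    fit_foce,
    ofv,
)
from escipk.pk_model import DoseEvent, PopulationParameters, Subject, concentration_profile


def _linear_engine(a, G1, G2, obs_subj, y, s2p, s2a, n_subj):
    """Engine over a model linear in eta (zero second derivatives)."""

    def predict(etas, second=False):
        e1 = etas[obs_subj, 0]
        e2 = etas[obs_subj, 1]
        f = a + G1 * e1 + G2 * e2
        if not second:
            return f, G1.copy(), G2.copy()
        z = np.zeros_like(f)
        return f, G1.copy(), G2.copy(), z, z, z

    predict.supports_second = True
    eng = FoceEngine(predict, y, obs_subj, n_subj)
    eng.set_variance(s2p, s2a, interaction=True)
    return eng


def _toy_pk_dataset(n_obs=6, spread=0.1, seed=7):
    """Two-subject oral PK dataset with informative sampling."""
    doses = [DoseEvent(24.0 * k, 10.0) for k in range(10)]
    rng = np.random.default_rng(seed)
    records = []
    for sid, mult in [("A", 0.85), ("B", 1.25)]:
        times = np.sort(rng.uniform(100, 230, n_obs))
        f = concentration_profile(doses, times, 16.3 * mult, 815.0, 0.6)
        concs = f * (1 + rng.normal(0, spread, n_obs))
        records.append(
            SubjectRecord(
                Subject(id=sid, age=45, genotype="*1/*1"),
                doses,
                [Observation(t, c) for t, c in zip(times, concs)],
            )
        )
    return PKDataset(records)


class TestLaplaceOracles:
    def test_linear_gaussian_ofv_is_exact(self):
        """For a model linear in eta with additive error, the conditional
        objective equals the closed-form marginal -2 log likelihood."""
        rng = np.random.default_rng(0)
        a = np.array([5.0, 3.0, 4.0, 6.0, 2.0, 7.0])
        G1 = np.array([1.0, 0.5, 2.0, 1.5, 0.3, 0.8])
        G2 = np.array([0.2, 1.0, 0.5, 0.7, 1.2, 0.4])
        obs_subj = np.array([0, 0, 1, 1, 2, 2])
        y = a + rng.normal(0, 1, 6)
        s2a = 0.5
        omega = np.diag([0.3, 0.7])
        eng = _linear_engine(a, G1, G2, obs_subj, y, 0.0, s2a, 3)
        ofv_i, _ = eng.subject_ofv(omega)

        closed = 0.0
        for i in range(3):
            m = obs_subj == i
            G = np.stack([G1[m], G2[m]], axis=1)
            S = G @ omega @ G.T + s2a * np.eye(int(m.sum()))
            r = y[m] - a[m]
            closed += np.log(np.linalg.det(2 * np.pi * S)) + r @ np.linalg.solve(S, r)
        assert ofv_i.sum() == pytest.approx(closed, abs=1e-9)

    def test_nonlinear_toy_matches_quadrature(self, truth):
        """FOCE-I OFV within 0.1 of the exact marginal -2LL (2-D quadrature)."""
        pop = PopulationParameters(
            tvcl=16.3, tvv=815.0, theta_age=0.0, theta_im=1.0, theta_pm=1.0,
            omega2_cl=0.04, omega2_v=0.05, sigma2_prop=0.02,
        )
        ds = _toy_pk_dataset()
        cfg = FitConfig()
        value = ofv(ds, pop, cfg)

        engine, model = est._engine_for(ds, pop, cfg)
        omega = np.diag([pop.omega2_cl, pop.omega2_v])
        oi = np.linalg.inv(omega)
        total = 0.0
        for i in range(2):
            m = model.obs_subj == i
            y = model.y[m]

            def integrand(e2, e1, m=m, y=y, i=i):
                etas = np.zeros((2, 2))
                etas[i] = [e1, e2]
                f = engine.predict(etas)[0][m]
                var = pop.sigma2_prop * f**2
                ll = -0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
                e = np.array([e1, e2])
                lp = -0.5 * (e @ oi @ e) - 0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(omega))
                return np.exp(ll + lp)

            lim1, lim2 = 4 * np.sqrt(pop.omega2_cl), 4 * np.sqrt(pop.omega2_v)
            val, _ = integrate.dblquad(integrand, -lim1, lim1, -lim2, lim2,
                                       epsabs=1e-13, epsrel=1e-8)
            total += -2.0 * np.log(val)
        assert value == pytest.approx(total, abs=0.1)


class TestConditionalEta:
    def _record_at_typical(self, pop):
        doses = [DoseEvent(24.0 * k, 10.0) for k in range(8)]
        times = [130.0, 150.0, 170.0]
        f = concentration_profile(doses, times, pop.tvcl, pop.tvv, pop.ka)
        return SubjectRecord(
            Subject(id="t", age=45, genotype="*1/*1"),
            doses,
            [Observation(t, c) for t, c in zip(times, f)],
        )

    def test_zero_residual_additive_gives_zero_eta(self):
        """Observations equal to typical predictions: the penalty is
        minimized at eta = 0 (additive-error model, exact)."""
        pop = PopulationParameters(
            theta_age=0.0, omega2_cl=0.1, omega2_v=0.2, sigma2_prop=0.0, sigma2_add=4.0,
        )
        eta, H = conditional_eta(self._record_at_typical(pop), pop,
                                 FitConfig(fix_sigma2_add=False))
        np.testing.assert_allclose(eta, 0.0, atol=1e-8)
        assert H[0, 0] > 0 and np.linalg.det(H) > 0

    def test_zero_residual_proportional_near_zero_eta(self):
        pop = PopulationParameters(theta_age=0.0, omega2_cl=0.1, omega2_v=0.2,
                                   sigma2_prop=0.03)
        eta, _ = conditional_eta(self._record_at_typical(pop), pop)
        assert np.abs(eta).max() < 0.05

    def test_infinite_shrinkage_as_omega_vanishes(self):
        pop = PopulationParameters(theta_age=0.0, omega2_cl=1e-8, omega2_v=1e-8,
                                   sigma2_prop=0.03)
        rec = self._record_at_typical(PopulationParameters(theta_age=0.0))
        # observations off-typical, but the prior dominates
        for o in rec.observations:
            o.conc *= 1.5
        eta, _ = conditional_eta(rec, pop)
        np.testing.assert_allclose(eta, 0.0, atol=1e-4)

    def test_matches_dense_grid_search(self):
        """eta_hat agrees with a two-stage dense grid over the penalized
        deviance to 1e-4 per component."""
        pop = PopulationParameters(theta_age=0.0, omega2_cl=0.09, omega2_v=0.2,
                                   sigma2_prop=0.03)
        rec = self._record_at_typical(PopulationParameters(theta_age=0.0))
        concs = [26.0, 31.0, 24.0]
        for o, c in zip(rec.observations, concs):
            o.conc = c
        eta_hat, _ = conditional_eta(rec, pop)

        cfg = FitConfig()
        engine, _ = est._engine_for(PKDataset([rec]), pop, cfg)
        omega = np.diag([0.09, 0.2])

        def pen(e1, e2):
            return engine.penalized_deviance(np.array([[e1, e2]]), omega)[0]

        coarse = np.linspace(-1.0, 1.0, 81)
        vals = np.array([[pen(a, b) for b in coarse] for a in coarse])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        fine1 = np.linspace(coarse[i] - 0.05, coarse[i] + 0.05, 101)
        fine2 = np.linspace(coarse[j] - 0.05, coarse[j] + 0.05, 101)
        vals = np.array([[pen(a, b) for b in fine2] for a in fine1])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        f1 = np.linspace(fine1[i] - 2e-3, fine1[i] + 2e-3, 81)
        f2 = np.linspace(fine2[j] - 2e-3, fine2[j] + 2e-3, 81)
        vals = np.array([[pen(a, b) for b in f2] for a in f1])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        assert eta_hat[0] == pytest.approx(f1[i], abs=1e-4)
        assert eta_hat[1] == pytest.approx(f2[j], abs=1e-4)


class TestOFV:
    def test_additivity_over_subjects(self, truth):
        ds = _toy_pk_dataset()
        rec = ds.records[0]
        twin = SubjectRecord(
            Subject(id="A2", age=rec.subject.age, genotype=rec.subject.genotype),
            rec.doses,
            rec.observations,
        )
        base = ofv(ds, truth)
        with_twin = ofv(PKDataset(ds.records + [twin]), truth)
        solo = ofv(PKDataset([rec]), truth)
        assert with_twin == pytest.approx(base + solo, abs=1e-8)

    def test_invariant_to_subject_order(self, small_dataset, truth):
        forward = ofv(small_dataset, truth)
        reversed_ds = PKDataset(list(reversed(small_dataset.records)))
        assert ofv(reversed_ds, truth) == pytest.approx(forward, abs=1e-8)

    def test_deterministic(self, small_dataset, truth):
        assert ofv(small_dataset, truth) == ofv(small_dataset, truth)


class TestFit:
    def test_near_noiseless_identifiability(self):
        """With vanishing variability the fixed effects are recovered ~exactly."""
        from escipk.synthetic_cohort import CohortConfig, generate_cohort, simulate_dataset

        gen = PopulationParameters(
            tvcl=16.3, tvv=815.0, theta_age=0.0, theta_im=1.0, theta_pm=1.0,
            omega2_cl=1e-8, omega2_v=1e-8, sigma2_prop=1e-6,
        )
        cohort = generate_cohort(
            CohortConfig(n_subjects=6, target_observations=24, postdose_fraction=0.5),
            seed=3,
        )
        ds = simulate_dataset(cohort, truth=gen, seed=4)
        fit = fit_foce(ds, config=FitConfig(covariates=()))
        assert fit.converged
        assert fit.estimates.tvcl == pytest.approx(16.3, rel=0.01)
        assert fit.estimates.tvv == pytest.approx(815.0, rel=0.01)

    def test_multistart_stability(self, small_dataset):
        """Two different starting points reach the same optimum."""
        f1 = fit_foce(small_dataset)
        f2 = fit_foce(small_dataset, init=PopulationParameters())
        assert abs(f1.ofv - f2.ofv) < 0.1
        assert f1.estimates.tvcl == pytest.approx(f2.estimates.tvcl, rel=0.01)
        assert f1.estimates.tvv == pytest.approx(f2.estimates.tvv, rel=0.01)

    def test_fixed_parameters_unchanged(self, small_dataset):
        fit = fit_foce(small_dataset)
        assert fit.estimates.ka == 0.6
        assert fit.estimates.sigma2_add == 0.0

    def test_adding_generating_covariate_lowers_ofv(self, small_dataset):
        """The phenotype effect is in the generating model, so the fitted
        base model can never beat the fitted phenotype model."""
        base = fit_foce(small_dataset, config=FitConfig(covariates=()))
        full = fit_foce(
            small_dataset,
            init=base.estimates,
            config=FitConfig(covariates=(est.PHENOTYPE_ON_CL,)),
        )
        assert full.ofv <= base.ofv + 1e-6

    def test_etas_shrink_with_growing_residual_error(self, small_dataset, truth):
        cfg = FitConfig()
        engine, _ = est._engine_for(small_dataset, truth, cfg)
        omega = np.diag([truth.omega2_cl, truth.omega2_v])
        eta_tight = engine.solve_etas(omega)
        engine.set_variance(truth.sigma2_prop * 30, 0.0, interaction=True)
        eta_loose = engine.solve_etas(omega)
        assert np.abs(eta_loose).mean() < np.abs(eta_tight).mean()


class TestRecoveryAcrossReplicates:
    def test_median_recovery_within_published_intervals(self, truth):
        """Median estimates over replicate synthetic cohorts stay inside
        the published bootstrap 95% intervals for every free parameter.

        Replicates use 80-subject cohorts (desk-scale version of the
        study design) started at the generating values.
        """
        from escipk.synthetic_cohort import CohortConfig, generate_cohort, simulate_dataset

        rows = []
        for seed in range(60, 65):
            cohort = generate_cohort(
                CohortConfig(n_subjects=80, target_observations=254), seed=seed
            )
            ds = simulate_dataset(cohort, truth=truth, seed=seed + 1000)
            fit = fit_foce(ds, init=truth)
            assert fit.converged
            e = fit.estimates
            rows.append([e.tvcl, e.tvv, e.theta_im, e.theta_pm, e.sigma2_prop])
        med = np.median(np.array(rows), axis=0)
        intervals = [(14.7, 18.2), (581.9, 1070.8), (0.74, 0.97), (0.38, 0.59), (0.0226, 0.0359)]
        for value, (lo, hi) in zip(med, intervals):
            assert lo <= value <= hi
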