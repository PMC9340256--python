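"""Validation battery: bootstrap, CWRES, NPDE, goodness-of-fit table."""

import numpy as np
import pytest

from escipk.estimation import (
    FitConfig,
    Observation,
    PKDataset,
    SubjectRecord,
    fit_foce,
)
from escipk.evaluation import bootstrap, cwres, gof_table, npde, simulate_observations
from escipk.pk_model import DoseEvent, PopulationParameters, Subject, concentration_profile
from escipk.synthetic_cohort import CohortConfig, generate_cohort, simulate_dataset


@pytest.fixture(scope="module")
def medium_fit(truth):
    """A 40-subject fit reused by the residual/NPDE tests."""
    cohort = generate_cohort(CohortConfig(n_subjects=40, target_observations=130), seed=31)
    ds = simulate_dataset(cohort, truth=truth, seed=32)
    fit = fit_foce(ds, init=truth)
    assert fit.converged
    return ds, fit


class TestBootstrap:
    def test_single_subject_rejected(self, truth):
        cohort = generate_cohort(CohortConfig(n_subjects=1, target_observations=4), seed=1)
        ds = simulate_dataset(cohort, truth=truth, seed=2)
        with pytest.raises(ValueError):
            bootstrap(ds, n=1, seed=0)

    def test_identity_resample_returns_original_estimates(self, truth):
        """A replicate that happens to redraw every subject exactly once
        reproduces the original fit."""
        cohort = generate_cohort(CohortConfig(n_subjects=3, target_observations=12), seed=3)
        ds = simulate_dataset(cohort, truth=truth, seed=4)
        cfg = FitConfig(covariates=())
        original = fit_foce(ds, init=truth, config=cfg)

        # find a seed whose first replicate draws the identity multiset
        seed = next(
            s
            for s in range(200)
            if sorted(np.random.default_rng(s).integers(0, 3, 3).tolist()) == [0, 1, 2]
        )
        res = bootstrap(ds, init=truth, config=cfg, n=1, seed=seed)
        assert res.n_failed == 0
        assert res.replicates["tvcl"].iloc[0] == pytest.approx(original.estimates.tvcl, rel=1e-3)
        assert res.replicates["tvv"].iloc[0] == pytest.approx(original.estimates.tvv, rel=1e-3)

    def test_percentile_interval_widens_with_noise(self, truth):
        """Doubling the residual variance in the generating model widens
        the bootstrap interval for the residual parameter."""
        cfg = FitConfig(covariates=())
        widths = []
        for factor, seed in [(1.0, 41), (6.0, 41)]:
            gen = truth.replace(sigma2_prop=truth.sigma2_prop * factor)
            cohort = generate_cohort(CohortConfig(n_subjects=14, target_observations=45), seed=42)
            ds = simulate_dataset(cohort, truth=gen, seed=43)
            res = bootstrap(ds, init=gen, config=cfg, n=8, seed=seed)
            s = res.summary.loc["sigma2_prop"]
            widths.append(s["ci_upper"] - s["ci_lower"])
        assert widths[1] > widths[0]

    def test_reproducible_given_seed(self, truth):
        cohort = generate_cohort(CohortConfig(n_subjects=6, target_observations=20), seed=5)
        ds = simulate_dataset(cohort, truth=truth, seed=6)
        cfg = FitConfig(covariates=())
        a = bootstrap(ds, init=truth, config=cfg, n=3, seed=77)
        b = bootstrap(ds, init=truth, config=cfg, n=3, seed=77)
        assert a.replicates.equals(b.replicates)


class TestCWRES:
    def _additive_fit(self):
        """A fit-like object with no IIV and additive error only."""
        pop = PopulationParameters(
            theta_age=0.0, theta_im=1.0, theta_pm=1.0,
            omega2_cl=0.0, omega2_v=0.0, sigma2_prop=0.0, sigma2_add=9.0,
        )
        doses = [DoseEvent(24.0 * k, 10.0) for k in range(8)]
        times = [120.0, 140.0, 165.0]
        f = concentration_profile(doses, times, pop.tvcl, pop.tvv, pop.ka)
        rng = np.random.default_rng(3)
        obs = [Observation(t, c + rng.normal(0, 3)) for t, c in zip(times, f)]
        ds = PKDataset([SubjectRecord(Subject(id="a", age=45, genotype="*1/*1"), doses, obs)])
        cfg = FitConfig(fix_sigma2_add=False)
        from escipk.estimation import FitResult, DatasetModel

        fit = FitResult(
            estimates=pop, extra_coefficients={}, ofv=0.0,
            etas=np.zeros((1, 2)), subject_ids=["a"], converged=True,
            n_function_evals=0, config=cfg, model=DatasetModel(ds, cfg),
        )
        return ds, fit, f

    def test_reduces_to_weighted_residuals_without_iiv(self):
        """With Omega = 0 and additive error, CWRES = (y - f)/sigma."""
        ds, fit, f = self._additive_fit()
        res = cwres(ds, fit)
        y = np.array([o.conc for o in ds.records[0].observations])
        np.testing.assert_allclose(res, (y - f) / 3.0, rtol=1e-6)

    def test_no_cross_subject_interference(self, medium_fit):
        """Each subject's CWRES depends only on its own records: permuting
        the subject order permutes the residual blocks unchanged.

        (Within a subject the lower-Cholesky decorrelation is
        order-dependent whenever the covariance is non-diagonal, so only
        cross-subject invariance holds in general.)
        """
        ds, fit = medium_fit
        base = cwres(ds, fit)
        order = list(reversed(range(ds.n_subjects)))
        ds2 = PKDataset([ds.records[i] for i in order])
        from dataclasses import replace

        fit2 = replace(fit, etas=fit.etas[order])
        res2 = cwres(ds2, fit2)
        # map each subject's block back
        counts = [sum(not o.blq for o in rec.observations) for rec in ds.records]
        starts = np.concatenate([[0], np.cumsum(counts)])
        got = {}
        pos = 0
        for i in order:
            got[i] = res2[pos : pos + counts[i]]
            pos += counts[i]
        for i in range(ds.n_subjects):
            np.testing.assert_allclose(got[i], base[starts[i] : starts[i] + counts[i]], rtol=1e-9)

    def test_standard_normal_scale_under_true_model(self, study_dataset, study_fit):
        """On data simulated from the fitted model, CWRES has mean ~0 and
        variance ~1 at the study's observation count."""
        res = cwres(study_dataset, study_fit)
        assert abs(res.mean()) < 0.15
        assert 0.8 <= res.var() <= 1.25


class TestGOF:
    def test_row_count_equals_quantifiable_observations(self, study_dataset, study_fit):
        table = gof_table(study_dataset, study_fit)
        assert len(table) == study_dataset.n_observations

    def test_time_after_dose_bounded_by_time(self, study_dataset, study_fit):
        table = gof_table(study_dataset, study_fit)
        assert (table["TAD"] >= 0).all()
        assert (table["TAD"] <= table["TIME"]).all()

    def test_noiseless_data_gives_pred_equals_dv(self):
        gen = PopulationParameters(
            theta_age=0.0, theta_im=1.0, theta_pm=1.0,
            omega2_cl=1e-10, omega2_v=1e-10, sigma2_prop=1e-8,
        )
        cohort = generate_cohort(CohortConfig(n_subjects=4, target_observations=14), seed=51)
        ds = simulate_dataset(cohort, truth=gen, seed=52)
        cfg = FitConfig(covariates=())
        from escipk.estimation import FitResult, DatasetModel

        fit = FitResult(
            estimates=gen, extra_coefficients={}, ofv=0.0,
            etas=np.zeros((4, 2)), subject_ids=ds.subject_ids, converged=True,
            n_function_evals=0, config=cfg, model=DatasetModel(ds, cfg),
        )
        table = gof_table(ds, fit)
        np.testing.assert_allclose(table["PRED"], table["DV"], rtol=1e-3)
        np.testing.assert_allclose(table["IPRED"], table["DV"], rtol=1e-3)


class TestNPDE:
    def test_requires_enough_simulations(self, medium_fit):
        ds, fit = medium_fit
        with pytest.raises(ValueError):
            npde(ds, fit, n_sim=50, seed=1)

    def test_self_consistency_under_true_model(self, medium_fit):
        """Observed data replaced by one simulated replicate: npde moments
        are those of a standard normal."""
        ds, fit = medium_fit
        sims, model = simulate_observations(ds, fit, 1, seed=99)
        replicate = sims[0]
        k = 0
        records = []
        for rec in ds.records:
            new_obs = []
            for o in rec.observations:
                if o.blq:
                    new_obs.append(o)
                else:
                    new_obs.append(Observation(o.time, max(replicate[k], 3.01)))
                    k += 1
            records.append(SubjectRecord(rec.subject, rec.doses, new_obs))
        ds_rep = PKDataset(records)
        res = npde(ds_rep, fit, n_sim=300, seed=5)
        assert abs(res.mean) < 0.25
        assert 0.7 <= res.variance <= 1.35
        assert np.isfinite(res.npde).all()

    def test_detects_gross_misspecification(self, medium_fit):
        """A model with clearance biased x2 is rejected by the global test."""
        ds, fit = medium_fit
        from dataclasses import replace

        biased = replace(fit, estimates=fit.estimates.replace(tvcl=fit.estimates.tvcl * 2))
        rejections = 0
        for seed in (11, 12, 13):
            res = npde(ds, biased, n_sim=200, seed=seed)
            rejections += res.p_global < 0.05
        assert rejections == 3

    def test_pvalues_are_probabilities(self, medium_fit):
        ds, fit = medium_fit
        res = npde(ds, fit, n_sim=200, seed=21)
        for p in (res.p_t, res.p_fisher, res.p_sw, res.p_global):
            assert 0.0 <= p <= 1.0

    def test_reproducible_given_seed(self, medium_fit):
        ds, fit = medium_fit
        a = npde(ds, fit, n_sim=150, seed=8)
        b = npde(ds, fit, n_sim=150, seed=8)
        np.testing.assert_array_equal(a.npde, b.npde)
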