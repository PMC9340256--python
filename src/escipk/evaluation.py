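"""Model validation: bootstrap, goodness-of-fit, CWRES and NPDE.

Four standard pharmacometric checks of a fitted population model:

* **Nonparametric bootstrap** — subjects resampled with replacement,
  the model refitted per replicate, parameter medians and percentile
  confidence intervals reported.
* **Goodness-of-fit table** — population predictions (PRED, eta = 0),
  individual predictions (IPRED, at the empirical-Bayes eta) and
  conditional weighted residuals per observation.
* **CWRES** — residuals decorrelated under the first-order expansion of
  the model about each subject's empirical-Bayes eta; approximately
  standard normal when the model fits.
* **NPDE** — simulation-based normalized prediction distribution
  errors: observations are decorrelated against the empirical mean and
  covariance of ``n_sim`` model-simulated replicates, rank-transformed
  and mapped through the inverse normal CDF; standard normal under the
  true model regardless of design.  The summary battery is a t-test for
  mean 0, a chi-square dispersion test for variance 1 and a
  Shapiro-Wilk normality test, with a Bonferroni-adjusted global p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    DatasetModel,
    FitConfig,
    FitResult,
    FoceEngine,
    PKDataset,
    _omega_matrix,
    _params_from_pop,
    fit_foce,
)

logger = logging.getLogger("escipk")

__all__ = [
    "BootstrapResult",
    "NPDEResult",
    "bootstrap",
    "cwres",
    "gof_table",
    "npde",
    "simulate_observations",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _fit_arrays(dataset: PKDataset, fit: FitResult):
    """(model, cl_base, v_base, params) for the dataset under the fitted model."""
    model = DatasetModel(dataset, fit.config)
    params = _params_from_pop(fit.estimates, fit.config)
    for key, value in fit.extra_coefficients.items():
        params["thetas"][key.split(":", 1)[1]] = value
    cl_base, v_base = model.bases(params)
    return model, cl_base, v_base, params


def simulate_observations(
    dataset: PKDataset,
    fit: FitResult,
    n_sim: int,
    seed=None,
    include_residual: bool = True,
):
    """Simulate ``n_sim`` replicate observation vectors under the fitted model.

    Each replicate redraws every subject's eta from N(0, Omega) and the
    proportional (and any additive) residual noise, on the original
    design (doses and sampling times).  Returns an (n_sim, n_obs) array
    aligned with the dataset's non-BLQ observations.
    """
    model, cl_base, v_base, params = _fit_arrays(dataset, fit)
    predict = model.predictor(cl_base, v_base, params["ka"])
    rng = np.random.default_rng(seed)
    est = fit.estimates
    sims = np.empty((n_sim, model.n_obs))
    for k in range(n_sim):
        etas = np.stack(
            [
                rng.normal(0.0, np.sqrt(est.omega2_cl), model.n_subj),
                rng.normal(0.0, np.sqrt(est.omega2_v), model.n_subj),
            ],
            axis=1,
        )
        f, _, _ = predict(etas)
        y = f.copy()
        if include_residual:
            y = f * (1.0 + rng.normal(0.0, np.sqrt(est.sigma2_prop), model.n_obs))
            if est.sigma2_add > 0:
                y += rng.normal(0.0, np.sqrt(est.sigma2_add), model.n_obs)
        sims[k] = y
    return sims, model


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    n_replicates: int
    n_failed: int
    replicates: pd.DataFrame  # one row per converged replicate
    summary: pd.DataFrame  # median and 2.5/97.5 percentiles per parameter

    def write_replicates(self, path) -> None:
        self.replicates.to_csv(path, index=False)


_PARAM_COLUMNS = {
    "tvcl": lambda e: e.tvcl,
    "tvv": lambda e: e.tvv,
    "theta_age": lambda e: e.theta_age,
    "theta_im": lambda e: e.theta_im,
    "theta_pm": lambda e: e.theta_pm,
    "omega2_cl": lambda e: e.omega2_cl,
    "omega2_v": lambda e: e.omega2_v,
    "sigma2_prop": lambda e: e.sigma2_prop,
}


def bootstrap(
    dataset: PKDataset,
    init=None,
    config: Optional[FitConfig] = None,
    n: int = 1000,
    seed=None,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the population fit.

    Resamples subjects with replacement to the original subject count
    (no stratification), refits every replicate, and summarizes each
    parameter by its median and percentile 95% interval over converged
    replicates.  Failed replicates are counted, not fatal.
    """
    if dataset.n_subjects < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for k in range(n):
        idx = rng.integers(0, dataset.n_subjects, dataset.n_subjects)
        records = []
        for j, i in enumerate(idx):
            rec = dataset.records[i]
            # relabel so resampled duplicates stay distinct subjects
            from dataclasses import replace as _replace

            records.append(
                type(rec)(
                    subject=_replace(rec.subject, id=f"B{k}_{j}"),
                    doses=rec.doses,
                    observations=rec.observations,
                )
            )
        try:
            fit = fit_foce(PKDataset(records), init=init, config=config)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", k, exc)
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        rows.append({name: get(fit.estimates) for name, get in _PARAM_COLUMNS.items()})
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "median": reps.median(),
            "ci_lower": reps.quantile(0.025),
            "ci_upper": reps.quantile(0.975),
        }
    )
    return BootstrapResult(
        n_replicates=n, n_failed=n_failed, replicates=reps, summary=summary
    )


# ---------------------------------------------------------------------------
# CWRES and goodness of fit
# ---------------------------------------------------------------------------


def cwres(dataset: PKDataset, fit: FitResult) -> np.ndarray:
    """Conditional weighted residuals, one per non-BLQ observation.

    First-order expansion about the empirical-Bayes eta: with G the
    eta-sensitivity of f at eta_hat,

        E   = f(eta_hat) - G eta_hat
        COV = G Omega G' + diag(sigma2_prop f(eta_hat)^2 + sigma2_add)
        CWRES = L^-1 (y - E),  L = chol(COV).
    """
    if fit.etas is None:
        raise ValueError("fit has no empirical-Bayes etas")
    model, cl_base, v_base, params = _fit_arrays(dataset, fit)
    predict = model.predictor(cl_base, v_base, params["ka"])
    est = fit.estimates
    omega = _omega_matrix(est.omega2_cl, est.omega2_v)
    f, g1, g2 = predict(fit.etas)
    var = est.sigma2_prop * f**2 + est.sigma2_add
    out = np.empty(model.n_obs)
    for i in range(model.n_subj):
        m = model.obs_subj == i
        G = np.stack([g1[m], g2[m]], axis=1)
        cov = G @ omega @ G.T + np.diag(var[m])
        resid = model.y[m] - (f[m] - G @ fit.etas[i])
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            jitter = 1e-8 * np.trace(cov) / max(cov.shape[0], 1)
            logger.warning("singular CWRES covariance for subject %d; jitter %.2e", i, jitter)
            L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        out[m] = np.linalg.solve(L, resid)
    return out


def gof_table(dataset: PKDataset, fit: FitResult) -> pd.DataFrame:
    """Observation-level goodness-of-fit table.

    Columns: subject id, time, time after last dose, observed DV, PRED
    (population prediction, eta = 0), IPRED (individual prediction at
    the empirical-Bayes eta) and CWRES.  One row per non-BLQ record.
    """
    model, cl_base, v_base, params = _fit_arrays(dataset, fit)
    predict = model.predictor(cl_base, v_base, params["ka"])
    pred = predict(np.zeros((model.n_subj, 2)))[0]
    ipred = predict(fit.etas)[0]
    res = cwres(dataset, fit)
    ids, times, tad = [], [], []
    for rec in dataset.records:
        dose_times = np.array([d.time for d in rec.doses])
        for o in rec.observations:
            if o.blq:
                continue
            ids.append(rec.subject.id)
            times.append(o.time)
            tad.append(o.time - dose_times[dose_times <= o.time].max())
    return pd.DataFrame(
        {
            "ID": ids,
            "TIME": times,
            "TAD": tad,
            "DV": model.y,
            "PRED": pred,
            "IPRED": ipred,
            "CWRES": res,
        }
    )


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NPDEResult:
    npde: np.ndarray
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    p_t: float
    p_fisher: float
    p_sw: float
    p_global: float

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "p_t": self.p_t,
            "p_fisher": self.p_fisher,
            "p_sw": self.p_sw,
            "p_global": self.p_global,
        }


def npde(
    dataset: PKDataset,
    fit: FitResult,
    n_sim: int = 1000,
    seed=None,
) -> NPDEResult:
    """Normalized prediction distribution errors and their test battery.

    Per subject, observed and simulated vectors are decorrelated with
    the empirical mean and lower-Cholesky factor of the simulated
    covariance; the pde of each observation is its rank among the
    simulations with a 1/(2 n_sim) continuity correction, and
    npde = Phi^-1(pde).  The global p is the Bonferroni-adjusted
    minimum of the t, dispersion and Shapiro-Wilk p-values.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable ranks")
    sims, model = simulate_observations(dataset, fit, n_sim, seed=seed)
    y = model.y
    pde = np.empty(model.n_obs)
    for i in range(model.n_subj):
        m = model.obs_subj == i
        S = sims[:, m]  # (n_sim, n_i)
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            jitter = 1e-8 * np.trace(cov) / max(cov.shape[0], 1)
            L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        y_dec = np.linalg.solve(L, y[m] - mu)
        s_dec = np.linalg.solve(L, (S - mu).T)  # (n_i, n_sim)
        pde[m] = (s_dec < y_dec[:, None]).mean(axis=1)
    # continuity correction and clipping of extreme ranks
    lo = 1.0 / (2.0 * n_sim)
    pde = np.clip(pde + lo, lo, 1.0 - lo)
    values = stats.norm.ppf(pde)

    n = values.size
    mean = float(values.mean())
    variance = float(values.var(ddof=1))
    p_t = float(stats.ttest_1samp(values, 0.0).pvalue)
    # two-sided chi-square dispersion test of variance 1
    chi = (n - 1) * variance
    p_lo = stats.chi2.cdf(chi, n - 1)
    p_fisher = float(2.0 * min(p_lo, 1.0 - p_lo))
    p_sw = float(stats.shapiro(values).pvalue)
    p_global = float(min(1.0, 3.0 * min(p_t, p_fisher, p_sw)))
    return NPDEResult(
        npde=values,
        mean=mean,
        variance=variance,
        skewness=float(stats.skew(values)),
        kurtosis=float(stats.kurtosis(values)),
        p_t=p_t,
        p_fisher=p_fisher,
        p_sw=p_sw,
        p_global=p_global,
    )
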