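"""FOCE-I estimation of the population PK model.

The marginal likelihood of a nonlinear mixed-effects model has no closed
form; this module implements the first-order conditional estimation with
interaction (FOCE-I) approximation as a Laplace-type approximation
evaluated at each subject's empirical-Bayes (conditional) random-effect
estimate.  Per subject i with observations ``y`` and prediction
``f(eta)``,

    pen_dev(eta) = sum_j [ (y_j - f_j(eta))^2 / var_j + log var_j ]
                   + eta' Omega^-1 eta,
    var_j        = sigma2_prop * f_j(eta)^2 + sigma2_add,

the conditional estimate ``eta_hat`` minimizes ``pen_dev`` (interaction:
the residual variance is evaluated at the conditional prediction, not at
eta = 0), and the subject's objective contribution is

    OFV_i = sum_j [ log(2*pi*var_j) + (y_j - f_j)^2 / var_j ]
            + log|Omega| + eta_hat' Omega^-1 eta_hat
            + log|H_i / 2|,

with ``H_i`` the first-order (Gauss-Newton) curvature of ``pen_dev`` at
``eta_hat`` -- the linearization FOCE performs, always positive definite
and smooth in the population parameters, and equal to the exact Hessian
whenever the model is linear in eta (so the objective is then exactly
the closed-form marginal -2 log likelihood).  The total OFV sums over
subjects and *includes* all 2*pi constants, so absolute values differ
from NONMEM's constant-free convention by ``n_obs * log(2*pi)`` while
OFV differences (the quantity used for covariate testing) are
identical.

The inner problem is solved for all subjects simultaneously with a
vectorized Levenberg-Marquardt iteration driven by analytic first- and
second-order eta-sensitivities of the closed-form concentration, always
started from the same deterministic data-driven point so the outer
objective is a true function of the population parameters.

Fixed effects and variances are optimized on the log scale (positivity);
continuous/binary covariate calibrators on the natural scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .pk_model import (
    CONC_SCALE,
    MULTIPLIER_FLOOR,
    DoseEvent,
    PopulationParameters,
    Subject,
)

logger = logging.getLogger("escipk")

VAR_FLOOR = 1e-12
OMEGA_FLOOR = 1e-10
INNER_GRAD_TOL = 1e-8
HESSIAN_FD_STEP = 1e-4

__all__ = [
    "Observation",
    "SubjectRecord",
    "PKDataset",
    "CovariateTerm",
    "AGE_ON_CL",
    "PHENOTYPE_ON_CL",
    "FitConfig",
    "FitResult",
    "DatasetModel",
    "FoceEngine",
    "conditional_eta",
    "ofv",
    "fit_foce",
]


# ---------------------------------------------------------------------------
# dataset containers
# ---------------------------------------------------------------------------


@dataclass
class Observation:
    """One concentration measurement: time (h since first dose), conc (ng/ml)."""

    time: float
    conc: float
    blq: bool = False


@dataclass
class SubjectRecord:
    subject: Subject
    doses: list[DoseEvent]
    observations: list[Observation]


@dataclass
class PKDataset:
    """Event-record dataset: per subject, dose events plus observations.

    BLQ (below 3 ng/ml LLOQ) records are carried but excluded from
    fitting; every subject must retain at least one quantifiable
    observation and one dose.
    """

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            sid = rec.subject.id
            if not rec.doses:
                raise ValueError(f"subject {sid}: no dose events")
            if not any(not o.blq for o in rec.observations):
                raise ValueError(f"subject {sid}: no quantifiable observations")
            t0 = min(d.time for d in rec.doses)
            for o in rec.observations:
                if o.time < t0:
                    raise ValueError(
                        f"subject {sid}: observation at t={o.time} precedes first dose"
                    )
                if not o.blq and o.conc <= 0:
                    raise ValueError(
                        f"subject {sid}: non-BLQ concentration must be positive"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    @property
    def n_observations(self) -> int:
        """Quantifiable (non-BLQ) observation count."""
        return sum(sum(not o.blq for o in rec.observations) for rec in self.records)

    @property
    def n_blq(self) -> int:
        return sum(sum(o.blq for o in rec.observations) for rec in self.records)

    @property
    def subject_ids(self) -> list:
        return [rec.subject.id for rec in self.records]


# ---------------------------------------------------------------------------
# covariate model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate effect on a structural parameter.

    kind 'continuous'  -> multiplier 1 + sign*theta*(x - center), one df;
    kind 'categorical' -> multiplier 1 + theta*x with x in {0, 1}, one df;
    kind 'phenotype'   -> CYP2C19 metabolizer class, two multipliers
                          (theta_IM, theta_PM; EM reference), two df.

    ``center=None`` means "use the dataset median", recomputed per
    dataset as the model is fitted.
    """

    parameter: str  # 'cl' or 'v'
    name: str
    kind: str
    center: Optional[float] = None
    sign: int = 1

    def __post_init__(self) -> None:
        if self.parameter not in ("cl", "v"):
            raise ValueError("parameter must be 'cl' or 'v'")
        if self.kind not in ("continuous", "categorical", "phenotype"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    @property
    def df(self) -> int:
        return 2 if self.kind == "phenotype" else 1

    @property
    def key(self) -> str:
        return f"{self.name}@{self.parameter}"


#: Age on clearance with the decreasing-in-age sign convention: a positive
#: calibrator encodes CL falling with age.  Centered at the published
#: cohort median (45 y) so the typical clearance refers to the same
#: reference subject as the published estimates; centering is a pure
#: reparameterization, so model fit and OFV differences are unaffected.
AGE_ON_CL = CovariateTerm("cl", "AGE", "continuous", center=45.0, sign=-1)

#: CYP2C19 metabolizer phenotype on clearance (EM reference, 2 df).
PHENOTYPE_ON_CL = CovariateTerm("cl", "CYP2C19", "phenotype")


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    ka and the additive residual variance are fixed by default (sparse
    trough-dominated sampling does not inform absorption; the residual
    model is purely proportional).
    """

    covariates: tuple = (AGE_ON_CL, PHENOTYPE_ON_CL)
    fix_ka: bool = True
    fix_sigma2_add: bool = True
    interaction: bool = True
    maxiter: int = 300
    gtol: float = 1e-3
    fd_step: float = 1e-6
    compute_se: bool = False
    multiplier_floor: float = MULTIPLIER_FLOOR

    def with_covariates(self, covariates) -> "FitConfig":
        return replace(self, covariates=tuple(covariates))


@dataclass
class FitResult:
    """Population estimates, OFV, empirical-Bayes etas and diagnostics."""

    estimates: PopulationParameters
    extra_coefficients: dict
    ofv: float
    etas: np.ndarray
    subject_ids: list
    converged: bool
    n_function_evals: int
    config: FitConfig
    model: "DatasetModel" = field(repr=False, default=None)
    se: Optional[dict] = None
    rse_percent: Optional[dict] = None
    message: str = ""

    def parameter_table(self):
        """Estimates (and RSE% when the covariance step ran) as a DataFrame."""
        import pandas as pd

        est = self.estimates
        rows = {
            "CL/F (L/h)": est.tvcl,
            "V/F (L)": est.tvv,
            "ka (1/h)": est.ka,
            "theta_age": est.theta_age,
            "theta_IM": est.theta_im,
            "theta_PM": est.theta_pm,
            "omega2_CL": est.omega2_cl,
            "omega2_V": est.omega2_v,
            "sigma2_prop": est.sigma2_prop,
            "sigma2_add": est.sigma2_add,
        }
        rows.update(self.extra_coefficients)
        df = pd.DataFrame({"estimate": rows})
        if self.rse_percent:
            df["rse_percent"] = [self.rse_percent.get(k, np.nan) for k in rows]
        return df


# ---------------------------------------------------------------------------
# dataset design: flattened arrays for batched prediction
# ---------------------------------------------------------------------------


class DatasetModel:
    """Flattened design linking a dataset to the covariate model.

    Precomputes, once per dataset, the (observation, dose) superposition
    pairs and per-subject covariate arrays so that predictions and their
    eta-sensitivities for *all* subjects are single vectorized
    expressions.
    """

    PHENO_CODE = {"EM": 0, "IM": 1, "PM": 2}

    def __init__(self, dataset: PKDataset, config: FitConfig):
        self.dataset = dataset
        self.config = config
        self.n_subj = dataset.n_subjects

        y, obs_subj = [], []
        pair_obs, pair_dt, pair_amt, pair_subj = [], [], [], []
        obs_idx = 0
        for i, rec in enumerate(dataset.records):
            dose_t = np.array([d.time for d in rec.doses])
            dose_a = np.array([d.amount for d in rec.doses])
            for o in rec.observations:
                if o.blq:
                    continue
                y.append(o.conc)
                obs_subj.append(i)
                mask = dose_t <= o.time
                k = int(mask.sum())
                pair_obs.extend([obs_idx] * k)
                pair_subj.extend([i] * k)
                pair_dt.extend(o.time - dose_t[mask])
                pair_amt.extend(dose_a[mask])
                obs_idx += 1
        self.y = np.asarray(y, float)
        self.obs_subj = np.asarray(obs_subj, int)
        self.n_obs = obs_idx
        self.pair_obs = np.asarray(pair_obs, int)
        self.pair_subj = np.asarray(pair_subj, int)
        self.pair_dt = np.asarray(pair_dt, float)
        self.pair_amt = np.asarray(pair_amt, float)

        # covariate arrays and centers, resolved against this dataset
        self.pheno_codes = None
        self.cov_values: dict[str, np.ndarray] = {}
        self.centers: dict[str, float] = {}
        # coefficient scales (covariate spreads) for outer-problem conditioning
        self.scales: dict[str, float] = {}
        for term in config.covariates:
            if term.kind == "phenotype":
                self.pheno_codes = np.array(
                    [self.PHENO_CODE[rec.subject.phenotype] for rec in dataset.records]
                )
            else:
                vals = self._covariate_array(term.name)
                self.cov_values[term.key] = vals
                if term.kind == "continuous":
                    self.centers[term.key] = (
                        float(np.median(vals)) if term.center is None else term.center
                    )
                self.scales[term.key] = max(float(np.std(vals)), 0.1)

    def _covariate_array(self, name: str) -> np.ndarray:
        raw = [rec.subject.covariate(name) for rec in self.dataset.records]
        vals = np.array([np.nan if v is None else float(v) for v in raw])
        missing = np.isnan(vals)
        if missing.any():
            med = float(np.nanmedian(vals))
            logger.info(
                "covariate %s: imputed %d missing value(s) to median %.4g",
                name,
                int(missing.sum()),
                med,
            )
            vals[missing] = med
        return vals

    # -- covariate-adjusted typical parameters ---------------------------

    def bases(self, params: dict) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject typical CL/F and V/F from the unpacked parameters."""
        floor = self.config.multiplier_floor
        cl = np.full(self.n_subj, params["tvcl"])
        v = np.full(self.n_subj, params["tvv"])
        for term in self.config.covariates:
            if term.kind == "phenotype":
                mult = np.choose(
                    self.pheno_codes,
                    [1.0, params["theta_im"], params["theta_pm"]],
                )
            else:
                x = self.cov_values[term.key]
                theta = params["thetas"][term.key]
                if term.kind == "continuous":
                    m = 1.0 + term.sign * theta * (x - self.centers[term.key])
                else:
                    m = 1.0 + term.sign * theta * x
                mult = np.clip(m, floor, None)
            if term.parameter == "cl":
                cl = cl * mult
            else:
                v = v * mult
        return cl, v

    def predictor(self, cl_base: np.ndarray, v_base: np.ndarray, ka: float) -> Callable:
        """Batched prediction function f(eta) with analytic eta-sensitivities.

        Returns ``predict(etas)`` mapping (n_subj, 2) random effects to
        per-observation predictions and derivatives with respect to
        eta_cl and eta_v.
        """
        return self._make_predict(
            self.pair_obs, self.pair_subj, self.pair_dt, self.pair_amt,
            self.n_obs, self.obs_subj, cl_base, v_base, ka,
        )

    def _make_predict(self, pair_obs, pair_subj, pair_dt, pair_amt, n_obs, obs_subj, cl_base, v_base, ka):
        scale = CONC_SCALE * pair_amt * ka

        def predict(etas: np.ndarray, second: bool = False):
            """Per-observation predictions and analytic eta-sensitivities.

            With ``second=True`` also returns the three per-observation
            second derivatives (cl-cl, cl-v, v-v), writing the dose
            kernel as (S/v) * psi(ke) with psi = (e^{-ke t} - e^{-ka t})
            / (ka - ke) and using d ke/d eta_cl = ke, d ke/d eta_v = -ke.
            """
            cl = cl_base * np.exp(etas[:, 0])
            v = v_base * np.exp(etas[:, 1])
            ke = cl / v
            # nudge off the removable ka == ke singularity
            ke = np.where(np.abs(ka - ke) < 1e-8 * ka, ke * (1.0 + 1e-7), ke)
            d = ka - ke
            ke_p = ke[pair_subj]
            d_p = d[pair_subj]
            v_p = v[pair_subj]
            e1 = np.exp(-ke_p * pair_dt)
            e2 = np.exp(-ka * pair_dt)
            diff = e1 - e2
            base = scale / v_p
            psi = diff / d_p
            psi1 = diff / d_p**2 - pair_dt * e1 / d_p
            contrib = base * psi
            kepsi1 = ke_p * psi1
            gcl_p = base * kepsi1
            gv_p = -contrib - base * kepsi1
            f = np.bincount(pair_obs, contrib, n_obs)
            g1 = np.bincount(pair_obs, gcl_p, n_obs)
            g2 = np.bincount(pair_obs, gv_p, n_obs)
            if not second:
                return f, g1, g2
            psi2 = (
                pair_dt**2 * e1 / d_p
                - 2.0 * pair_dt * e1 / d_p**2
                + 2.0 * diff / d_p**3
            )
            ke2psi2 = ke_p**2 * psi2
            c_uu = base * (ke2psi2 + kepsi1)
            c_uw = -base * (2.0 * kepsi1 + ke2psi2)
            c_ww = base * (psi + 3.0 * kepsi1 + ke2psi2)
            f11 = np.bincount(pair_obs, c_uu, n_obs)
            f12 = np.bincount(pair_obs, c_uw, n_obs)
            f22 = np.bincount(pair_obs, c_ww, n_obs)
            return f, g1, g2, f11, f12, f22

        def subset(subj_idx: np.ndarray):
            """Restrict the predictor to a subject subset (renumbered)."""
            subj_idx = np.asarray(subj_idx)
            n_sub = len(subj_idx)
            obs_ids = np.where(np.isin(obs_subj, subj_idx))[0]
            obs_remap = np.full(n_obs, -1)
            obs_remap[obs_ids] = np.arange(len(obs_ids))
            subj_remap = np.full(len(cl_base), -1)
            subj_remap[subj_idx] = np.arange(n_sub)
            pmask = np.isin(pair_subj, subj_idx)
            sub_predict = self._make_predict(
                obs_remap[pair_obs[pmask]],
                subj_remap[pair_subj[pmask]],
                pair_dt[pmask],
                pair_amt[pmask],
                len(obs_ids),
                subj_remap[obs_subj[obs_ids]],
                cl_base[subj_idx],
                v_base[subj_idx],
                ka,
            )
            return sub_predict, obs_ids

        predict.supports_second = True
        predict.subset = subset
        return predict


# ---------------------------------------------------------------------------
# conditional (inner) problem and Laplace objective
# ---------------------------------------------------------------------------


class FoceEngine:
    """Batched conditional-eta solver and Laplace/FOCE-I objective.

    Generic over the prediction function: ``predict(etas)`` must return
    per-observation predictions and their two eta-sensitivities for all
    subjects at once.  The PK model supplies one such predictor
    (:meth:`DatasetModel.predictor`); tests may supply e.g. a linear one.
    """

    def __init__(self, predict: Callable, y: np.ndarray, obs_subj: np.ndarray, n_subj: int):
        self.predict = predict
        self.y = np.asarray(y, float)
        self.obs_subj = np.asarray(obs_subj, int)
        self.n_subj = n_subj
        self.var_fixed: Optional[np.ndarray] = None
        self.s2p = 0.0
        self.s2a = 0.0
        self.inner_flags = np.zeros(n_subj, dtype=bool)  # true = inner non-convergence
        #: predictor provides analytic second derivatives
        self.analytic_hessian = bool(getattr(predict, "supports_second", False))

    def set_variance(self, sigma2_prop: float, sigma2_add: float, interaction: bool = True):
        """Configure the residual-variance model.

        With ``interaction=False`` (plain FOCE) the variance is frozen at
        the eta = 0 prediction instead of following the conditional one.
        """
        self.s2p = float(sigma2_prop)
        self.s2a = float(sigma2_add)
        if interaction:
            self.var_fixed = None
        else:
            f0, _, _ = self.predict(np.zeros((self.n_subj, 2)))
            self.var_fixed = np.maximum(self.s2p * f0**2 + self.s2a, VAR_FLOOR)

    # -- penalized deviance and its analytic gradient --------------------

    def _terms(self, etas: np.ndarray, omega_inv: np.ndarray):
        f, g1, g2 = self.predict(etas)
        r = self.y - f
        if self.var_fixed is not None:
            var = self.var_fixed
            w = -2.0 * r / var
        else:
            var = np.maximum(self.s2p * f * f + self.s2a, VAR_FLOOR)
            w = (-2.0 * r / var) + 2.0 * self.s2p * f * (1.0 / var - r * r / (var * var))
        per_obs = r * r / var + np.log(var)
        obj = np.bincount(self.obs_subj, per_obs, self.n_subj)
        obj += np.einsum("ij,jk,ik->i", etas, omega_inv, etas)
        grad = np.stack(
            [
                np.bincount(self.obs_subj, w * g1, self.n_subj),
                np.bincount(self.obs_subj, w * g2, self.n_subj),
            ],
            axis=1,
        )
        grad += 2.0 * etas @ omega_inv
        return obj, grad, f, var, r, g1, g2

    def penalized_deviance(self, etas: np.ndarray, omega: np.ndarray) -> np.ndarray:
        omega_inv = np.linalg.inv(omega)
        return self._terms(etas, omega_inv)[0]

    def _gn_hessian(self, var, g1, g2, omega_inv):
        wh = 2.0 / var
        h11 = np.bincount(self.obs_subj, wh * g1 * g1, self.n_subj) + 2 * omega_inv[0, 0]
        h22 = np.bincount(self.obs_subj, wh * g2 * g2, self.n_subj) + 2 * omega_inv[1, 1]
        h12 = np.bincount(self.obs_subj, wh * g1 * g2, self.n_subj) + 2 * omega_inv[0, 1]
        return h11, h12, h22

    def subset_engine(self, subj_idx: np.ndarray) -> Optional["FoceEngine"]:
        """Engine restricted to a subject subset, or None if unsupported."""
        subset = getattr(self.predict, "subset", None)
        if subset is None:
            return None
        predict_sub, obs_ids = subset(subj_idx)
        subj_remap = {int(s): k for k, s in enumerate(subj_idx)}
        obs_subj_sub = np.array([subj_remap[int(s)] for s in self.obs_subj[obs_ids]])
        eng = FoceEngine(predict_sub, self.y[obs_ids], obs_subj_sub, len(subj_idx))
        eng.s2p, eng.s2a = self.s2p, self.s2a
        if self.var_fixed is not None:
            eng.var_fixed = self.var_fixed[obs_ids]
        return eng

    def _default_start(self) -> np.ndarray:
        """Data-driven Newton start: match each subject's mean level.

        Trough-dominated concentrations scale roughly inversely with
        clearance, so eta_cl = log(mean f(0) / mean y) puts most
        subjects within one step of their conditional mode.
        """
        f0, _, _ = self.predict(np.zeros((self.n_subj, 2)))
        fbar = np.bincount(self.obs_subj, f0, self.n_subj)
        ybar = np.bincount(self.obs_subj, self.y, self.n_subj)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((ybar > 0) & (fbar > 0), fbar / ybar, 1.0)
        eta = np.zeros((self.n_subj, 2))
        eta[:, 0] = np.clip(np.log(ratio), -2.5, 2.5)
        return eta

    def solve_etas(
        self,
        omega: np.ndarray,
        eta0: Optional[np.ndarray] = None,
        tol: float = INNER_GRAD_TOL,
        max_iter: int = 80,
    ) -> np.ndarray:
        """Empirical-Bayes eta for every subject.

        Sparse sampling can leave several shallow conditional modes per
        subject (dose-superposition timing), so the Newton solve runs
        from a small fixed set of deterministic starts — the data-driven
        point and two eta_v offsets bracketing the volume valley — and
        keeps each subject's best basin.  Taking the per-subject minimum
        over fixed starts keeps the objective a deterministic function
        of the population parameters (no dependence on evaluation
        history); ``eta0``, when given, is only an extra candidate that
        must beat the default basins.  Stragglers left unconverged by
        the batched Newton are polished one at a time and flagged if
        still unconverged.
        """
        omega_inv = np.linalg.inv(omega)
        eta = self._newton(self._default_start(), omega, tol, max_iter)
        obj = self._terms(eta, omega_inv)[0]
        if eta0 is not None:
            cand = self._newton(np.asarray(eta0, float).copy(), omega, tol, max_iter)
            o = self._terms(cand, omega_inv)[0]
            take = o < obj - 1e-10
            if take.any():
                eta = np.where(take[:, None], cand, eta)
        _, grad, *_ = self._terms(eta, omega_inv)
        bad = np.abs(grad).max(axis=1) > 1e-6
        if bad.any():
            eta = self._polish_stragglers(eta, np.where(bad)[0], omega_inv, tol)
            _, grad, *_ = self._terms(eta, omega_inv)
            bad = np.abs(grad).max(axis=1) > 1e-6
        self.inner_flags = bad
        if bad.any():
            logger.debug("inner eta search not fully converged for %d subject(s)", bad.sum())
        return eta

    def _polish_stragglers(self, eta, idx, omega_inv, tol):
        """Per-subject derivative-free rescue for hard conditional problems."""
        from scipy import optimize as _opt

        eta = eta.copy()
        idx = np.asarray(idx)
        sub = self.subset_engine(idx)
        if sub is None:
            return eta
        omega = np.linalg.inv(omega_inv)
        for k, i in enumerate(idx):
            one = sub.subset_engine(np.array([k]))
            if one is None:
                continue

            def fun(e2):
                return one._terms(e2[None, :], omega_inv)[0][0]

            # cheap continuation first; derivative-free search only if needed
            cand = one._newton(eta[i][None, :], omega, tol, 300)[0]
            if fun(cand) <= fun(eta[i]):
                eta[i] = cand
            if np.abs(one._terms(eta[i][None, :], omega_inv)[1][0]).max() <= 1e-6:
                continue
            res = _opt.minimize(fun, eta[i], method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 120})
            if res.fun < fun(eta[i]):
                eta[i] = one._newton(res.x[None, :], omega, tol, 100)[0]
        return eta

    def _fd_hessians(self, etas, omega_inv, step=HESSIAN_FD_STEP):
        H = np.empty((self.n_subj, 2, 2))
        for k in range(2):
            dp = np.zeros_like(etas)
            dp[:, k] = step
            _, gp, *_ = self._terms(etas + dp, omega_inv)
            _, gm, *_ = self._terms(etas - dp, omega_inv)
            H[:, :, k] = (gp - gm) / (2 * step)
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    def _hessians(self, etas, omega_inv):
        """Per-subject Hessians of the penalized deviance.

        Analytic (exact and smooth in the outer parameters) when the
        predictor supplies second derivatives; finite differences of the
        analytic gradient otherwise.
        """
        if not self.analytic_hessian:
            return self._fd_hessians(etas, omega_inv)
        f, g1, g2, f11, f12, f22 = self.predict(etas, second=True)
        r = self.y - f
        if self.var_fixed is not None:
            var = self.var_fixed
            phi1 = -2.0 * r / var
            phi2 = 2.0 / var
        else:
            var = np.maximum(self.s2p * f * f + self.s2a, VAR_FLOOR)
            v2 = var * var
            s2p = self.s2p
            phi1 = -2.0 * r / var - 2.0 * s2p * f * r * r / v2 + 2.0 * s2p * f / var
            phi2 = (
                2.0 / var
                + 8.0 * s2p * f * r / v2
                - 2.0 * s2p * r * r / v2
                + 8.0 * s2p**2 * f * f * r * r / (v2 * var)
                + 2.0 * s2p / var
                - 4.0 * s2p**2 * f * f / v2
            )
        n = self.n_subj
        H = np.empty((n, 2, 2))
        H[:, 0, 0] = np.bincount(self.obs_subj, phi2 * g1 * g1 + phi1 * f11, n) + 2 * omega_inv[0, 0]
        H[:, 0, 1] = np.bincount(self.obs_subj, phi2 * g1 * g2 + phi1 * f12, n) + 2 * omega_inv[0, 1]
        H[:, 1, 0] = H[:, 0, 1]
        H[:, 1, 1] = np.bincount(self.obs_subj, phi2 * g2 * g2 + phi1 * f22, n) + 2 * omega_inv[1, 1]
        return H

    def _newton(self, eta, omega, tol, max_iter):
        """Levenberg-Marquardt iteration on the penalized deviance.

        All subjects advance simultaneously with per-subject adaptive
        damping of the exact (analytic where available) Hessian: an
        accepted step relaxes the damping toward pure Newton (quadratic
        tail convergence), a rejected one raises it toward scaled
        gradient descent, which traverses curved likelihood valleys
        without the stalls a backtracking line search suffers there.
        Slow stragglers are handed to a subsetted engine so the batch
        stops paying full cost for a few hard subjects.
        """
        omega_inv = np.linalg.inv(omega)
        eta = np.asarray(eta, float).copy()
        obj, grad, f, var, r, g1, g2 = self._terms(eta, omega_inv)
        lam = np.full(self.n_subj, 1e-2)
        active = np.ones(self.n_subj, dtype=bool)
        for it in range(max_iter):
            gnorm = np.abs(grad).max(axis=1)
            active &= gnorm > tol
            if not active.any():
                break
            if it >= 6 and self.n_subj > 8 and active.sum() <= max(2, self.n_subj // 6):
                idx = np.where(active)[0]
                sub = self.subset_engine(idx)
                if sub is not None:
                    eta[idx] = sub._newton(eta[idx], omega, tol, min(max_iter * 10, 400))
                    break
            H = self._hessians(eta, omega_inv)
            h11, h12, h22 = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
            d1 = np.abs(h11) + 1e-9
            d2 = np.abs(h22) + 1e-9
            for _ in range(2):
                a = h11 + lam * d1
                c = h22 + lam * d2
                b = h12
                det = a * c - b * b
                bad = active & ((det <= 0) | (a <= 0))
                if not bad.any():
                    break
                lam[bad] *= 10.0
            still = (det <= 0) | (a <= 0)
            if still.any():
                # pure scaled gradient-descent step for pathological curvature
                a = np.where(still, d1 * (1.0 + lam), a)
                c = np.where(still, d2 * (1.0 + lam), c)
                b = np.where(still, 0.0, b)
                det = a * c - b * b
            s1 = -(c * grad[:, 0] - b * grad[:, 1]) / det
            s2 = -(a * grad[:, 1] - b * grad[:, 0]) / det
            step = np.stack([s1, s2], axis=1)
            norm = np.abs(step).max(axis=1)
            big = norm > 3.0
            if big.any():
                step[big] *= (3.0 / norm[big])[:, None]
            # no representable progress left: treat as converged
            tiny = active & (np.abs(step).max(axis=1) < 1e-12)
            if tiny.any():
                active &= ~tiny
                if not active.any():
                    break
            eta_try = np.where(active[:, None], eta + step, eta)
            obj_t, grad_t, f_t, var_t, r_t, g1_t, g2_t = self._terms(eta_try, omega_inv)
            acc = active & (obj_t <= obj)
            lam = np.where(acc, np.maximum(lam / 3.0, 1e-10), np.where(active, lam * 7.0, lam))
            if acc.any():
                acc_o = acc[self.obs_subj]
                eta = np.where(acc[:, None], eta_try, eta)
                obj = np.where(acc, obj_t, obj)
                grad = np.where(acc[:, None], grad_t, grad)
                f = np.where(acc_o, f_t, f)
                var = np.where(acc_o, var_t, var)
                r = np.where(acc_o, r_t, r)
                g1 = np.where(acc_o, g1_t, g1)
                g2 = np.where(acc_o, g2_t, g2)
        return eta

    # -- Laplace objective ------------------------------------------------

    def eta_hessians(self, etas: np.ndarray, omega: np.ndarray):
        """Per-subject Hessians of the penalized deviance at ``etas``.

        Analytic when available; otherwise central finite differences of
        the analytic gradient, which are exact (to rounding) for
        objectives quadratic in eta.
        """
        return self._hessians(etas, np.linalg.inv(omega))

    def subject_ofv(self, omega: np.ndarray, eta0: Optional[np.ndarray] = None):
        """Per-subject -2 log (approximate) marginal likelihood contributions.

        Returns ``(ofv_i, eta_hat)``.
        """
        eta = self.solve_etas(omega, eta0=eta0)
        omega_inv = np.linalg.inv(omega)
        obj, grad, f, var, r, g1, g2 = self._terms(eta, omega_inv)
        data_term = np.bincount(
            self.obs_subj, r * r / var + np.log(2.0 * np.pi * var), self.n_subj
        )
        quad = np.einsum("ij,jk,ik->i", eta, omega_inv, eta)
        sign, log_det_omega = np.linalg.slogdet(omega)
        # FOCE(-I) linearizes the model about eta_hat: the determinant term
        # uses the first-order (Gauss-Newton) curvature, which is always
        # positive definite and smooth in the population parameters, and
        # coincides with the exact Hessian whenever f is linear in eta.
        h11, h12, h22 = self._gn_hessian(var, g1, g2, omega_inv)
        det = h11 * h22 - h12 * h12
        log_det_h_half = np.log(det / 4.0)
        ofv_i = data_term + log_det_omega + quad + log_det_h_half
        return ofv_i, eta


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _omega_matrix(omega2_cl: float, omega2_v: float) -> np.ndarray:
    return np.diag([max(omega2_cl, OMEGA_FLOOR), max(omega2_v, OMEGA_FLOOR)])


def _params_from_pop(pop: PopulationParameters, config: FitConfig) -> dict:
    thetas = {}
    for term in config.covariates:
        if term.kind == "phenotype":
            continue
        if term.name == "AGE" and term.parameter == "cl":
            thetas[term.key] = pop.theta_age
        else:
            thetas[term.key] = 0.0
    return {
        "tvcl": pop.tvcl,
        "tvv": pop.tvv,
        "ka": pop.ka,
        "theta_im": pop.theta_im,
        "theta_pm": pop.theta_pm,
        "omega2_cl": pop.omega2_cl,
        "omega2_v": pop.omega2_v,
        "sigma2_prop": pop.sigma2_prop,
        "sigma2_add": pop.sigma2_add,
        "thetas": thetas,
    }


def _engine_for(dataset: PKDataset, pop: PopulationParameters, config: FitConfig):
    model = DatasetModel(dataset, config)
    params = _params_from_pop(pop, config)
    cl_base, v_base = model.bases(params)
    engine = FoceEngine(model.predictor(cl_base, v_base, pop.ka), model.y, model.obs_subj, model.n_subj)
    engine.set_variance(pop.sigma2_prop, pop.sigma2_add, interaction=config.interaction)
    return engine, model


def conditional_eta(
    subject_data: SubjectRecord,
    pop: PopulationParameters,
    config: Optional[FitConfig] = None,
):
    """Empirical-Bayes eta and inner-problem curvature for one subject."""
    config = config or FitConfig()
    ds = PKDataset([subject_data])
    engine, _ = _engine_for(ds, pop, config)
    omega = _omega_matrix(pop.omega2_cl, pop.omega2_v)
    eta = engine.solve_etas(omega)
    H = engine.eta_hessians(eta, omega)
    if engine.inner_flags[0]:
        logger.warning("subject %s: conditional eta search flagged", subject_data.subject.id)
    return eta[0], H[0]


def ofv(dataset: PKDataset, pop: PopulationParameters, config: Optional[FitConfig] = None) -> float:
    """FOCE-I objective function value of ``pop`` on ``dataset``.

    Deterministic given inputs; includes the 2*pi constants (see module
    docstring), so only OFV *differences* are comparable with
    constant-free conventions.
    """
    config = config or FitConfig()
    engine, _ = _engine_for(dataset, pop, config)
    omega = _omega_matrix(pop.omega2_cl, pop.omega2_v)
    ofv_i, _ = engine.subject_ofv(omega)
    return float(ofv_i.sum())


# -- parameter packing -------------------------------------------------------


class _Packer:
    """Maps between the free-parameter vector and named natural-scale values.

    Covariate calibrators are rescaled by the covariate spread so every
    free parameter has comparable curvature in the outer problem.
    """

    def __init__(self, config: FitConfig, scales: Optional[dict] = None):
        self.config = config
        self.scales = scales or {}
        self.names: list[str] = ["log_tvcl", "log_tvv"]
        if not config.fix_ka:
            self.names.append("log_ka")
        self.has_phenotype = False
        for term in config.covariates:
            if term.kind == "phenotype":
                self.has_phenotype = True
                self.names += ["log_theta_im", "log_theta_pm"]
            else:
                self.names.append(f"theta:{term.key}")
        self.names += ["log_omega2_cl", "log_omega2_v", "log_sigma2_prop"]
        if not config.fix_sigma2_add:
            self.names.append("log_sigma2_add")

    @property
    def n(self) -> int:
        return len(self.names)

    def pack(self, params: dict) -> np.ndarray:
        x = []
        for name in self.names:
            if name.startswith("theta:"):
                key = name.split(":", 1)[1]
                x.append(params["thetas"][key] * self.scales.get(key, 1.0))
            elif name == "log_theta_im":
                x.append(math.log(params["theta_im"]))
            elif name == "log_theta_pm":
                x.append(math.log(params["theta_pm"]))
            else:
                x.append(math.log(max(params[name[4:]], 1e-12)))
        return np.array(x)

    def unpack(self, x: np.ndarray, fixed: dict) -> dict:
        params = dict(fixed)
        params["thetas"] = dict(fixed.get("thetas", {}))
        for name, v in zip(self.names, x):
            if name.startswith("theta:"):
                key = name.split(":", 1)[1]
                params["thetas"][key] = v / self.scales.get(key, 1.0)
            elif name == "log_theta_im":
                params["theta_im"] = math.exp(v)
            elif name == "log_theta_pm":
                params["theta_pm"] = math.exp(v)
            else:
                params[name[4:]] = math.exp(v)
        return params

    def bounds(self) -> list[tuple]:
        b = []
        for name in self.names:
            if name.startswith("theta:"):
                b.append((-10.0, 10.0))
            elif name in ("log_theta_im", "log_theta_pm"):
                b.append((math.log(0.02), math.log(50.0)))
            elif name.startswith("log_omega2") or name.startswith("log_sigma2"):
                b.append((math.log(1e-8), math.log(50.0)))
            else:
                b.append((math.log(1e-4), math.log(1e7)))
        return b


def fit_foce(
    dataset: PKDataset,
    init: Optional[PopulationParameters] = None,
    config: Optional[FitConfig] = None,
    init_extra: Optional[dict] = None,
) -> FitResult:
    """Fit the population model by minimizing the FOCE-I objective.

    Fixed quantities (ka, additive error) are declared in ``config``.
    Transformed free parameters are optimized with L-BFGS-B over a
    warm-started inner problem (each objective evaluation re-solves the
    conditional etas starting from the previous outer iterate's).
    """
    config = config or FitConfig()
    if init is None:
        # neutral, covariate-free starting point
        init = PopulationParameters(
            tvcl=10.0,
            tvv=400.0,
            theta_age=0.0,
            theta_im=1.0,
            theta_pm=1.0,
            omega2_cl=0.1,
            omega2_v=0.1,
            sigma2_prop=0.05,
        )
    model = DatasetModel(dataset, config)
    packer = _Packer(config, model.scales)
    params0 = _params_from_pop(init, config)
    if init_extra:
        params0["thetas"].update(init_extra)
    if not packer.has_phenotype:
        params0["theta_im"] = params0["theta_pm"] = 1.0
    fixed = {
        "ka": init.ka,
        "sigma2_add": init.sigma2_add,
        "theta_im": params0["theta_im"],
        "theta_pm": params0["theta_pm"],
        "thetas": params0["thetas"],
    }
    x0 = packer.pack(params0)

    eta_cache = {"etas": None}
    evals = {"n": 0}

    def objective(x: np.ndarray) -> float:
        evals["n"] += 1
        params = packer.unpack(x, fixed)
        try:
            cl_base, v_base = model.bases(params)
            engine = FoceEngine(
                model.predictor(cl_base, v_base, params["ka"]),
                model.y,
                model.obs_subj,
                model.n_subj,
            )
            engine.set_variance(
                params["sigma2_prop"], params["sigma2_add"], interaction=config.interaction
            )
            omega = _omega_matrix(params["omega2_cl"], params["omega2_v"])
            # deterministic: the inner solve never depends on evaluation
            # history, so the outer objective is a true function of x
            ofv_i, eta = engine.subject_ofv(omega)
            value = float(ofv_i.sum())
            if not np.isfinite(value):
                return 1e10
            eta_cache["etas"] = eta
            return value
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e10

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=packer.bounds(),
            options={
                "maxiter": config.maxiter,
                "ftol": 1e-10,
                "gtol": config.gtol,
                "eps": config.fd_step,
            },
        )
        # an abnormal line-search exit is usually recoverable: restart
        # with a fresh quasi-Newton memory from the best point so far;
        # a restart that no longer improves marks a stable optimum
        stable = bool(res.success)
        for _ in range(2):
            if res.success:
                stable = True
                break
            res2 = optimize.minimize(
                objective,
                res.x,
                method="L-BFGS-B",
                bounds=packer.bounds(),
                options={
                    "maxiter": config.maxiter,
                    "ftol": 1e-10,
                    "gtol": config.gtol,
                    "eps": config.fd_step,
                },
            )
            if res2.fun <= res.fun:
                stable = res.fun - res2.fun < 0.05
                res = res2
                if stable and not res.success:
                    break
            else:
                stable = True  # no further progress possible
                break
    x_hat = res.x
    params_hat = packer.unpack(x_hat, fixed)
    final_ofv = objective(x_hat)  # refresh eta cache at the optimum

    # final empirical-Bayes etas at the optimum
    etas = eta_cache["etas"]

    age_term = next(
        (t for t in config.covariates if t.kind == "continuous" and t.name == "AGE" and t.parameter == "cl"),
        None,
    )
    estimates = PopulationParameters(
        tvcl=params_hat["tvcl"],
        tvv=params_hat["tvv"],
        ka=params_hat["ka"],
        theta_age=params_hat["thetas"].get(age_term.key, 0.0) if age_term else 0.0,
        theta_im=params_hat["theta_im"] if packer.has_phenotype else 1.0,
        theta_pm=params_hat["theta_pm"] if packer.has_phenotype else 1.0,
        omega2_cl=params_hat["omega2_cl"],
        omega2_v=params_hat["omega2_v"],
        sigma2_prop=params_hat["sigma2_prop"],
        sigma2_add=params_hat["sigma2_add"],
        age_center=model.centers.get(age_term.key, 45.0) if age_term else 45.0,
        age_sign=age_term.sign if age_term else -1,
    )
    extra = {
        f"theta:{k}": v
        for k, v in params_hat["thetas"].items()
        if not (age_term and k == age_term.key)
    }

    result = FitResult(
        estimates=estimates,
        extra_coefficients=extra,
        ofv=float(final_ofv),
        etas=etas,
        subject_ids=dataset.subject_ids,
        converged=(bool(res.success) or stable) and final_ofv < 1e9,
        n_function_evals=evals["n"],
        config=config,
        model=model,
        message=str(res.message),
    )

    if config.compute_se:
        se, rse = _covariance_step(objective, x_hat, packer, params_hat)
        result.se = se
        result.rse_percent = rse
    return result


def _covariance_step(objective, x_hat, packer: _Packer, params_hat: dict):
    """Standard errors from the finite-difference Hessian of the objective.

    cov(theta_hat) = 2 * H^-1 for an OFV (-2 log L) objective; log-scale
    SEs are mapped to the natural scale by the delta method.
    """
    n = packer.n
    h = 1e-3
    H = np.zeros((n, n))
    f0 = objective(x_hat)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = objective(x_hat + e)
        fm[i] = objective(x_hat - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = objective(x_hat + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    try:
        cov = 2.0 * np.linalg.inv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        logger.warning("covariance step failed: singular Hessian")
        return None, None
    var = np.diag(cov)
    if np.any(var < 0):
        logger.warning("covariance step failed: negative variance")
        return None, None
    se_x = np.sqrt(var)
    se, rse = {}, {}
    for name, s, xv in zip(packer.names, se_x, x_hat):
        if name.startswith("theta:"):
            sc = packer.scales.get(name.split(":", 1)[1], 1.0)
            natural = xv / sc
            se_nat = s / sc
        else:
            natural = math.exp(xv)
            se_nat = s * natural  # delta method for log-scale parameters
        se[name] = se_nat
        rse[name] = 100.0 * se_nat / abs(natural) if natural != 0 else np.inf
    return se, rse
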