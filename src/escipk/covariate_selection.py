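"""Stepwise covariate search by likelihood-ratio OFV differences.

Forward inclusion adds, one at a time, the candidate covariate whose
addition lowers the objective function value the most, provided the drop
exceeds the inclusion threshold (default 6.63, the chi-square 1-df 1%
critical value).  Backward elimination then removes, one at a time, the
retained covariate whose removal raises the OFV the least, as long as
that rise stays below the stricter retention threshold (default 10.83,
chi-square 1-df 0.1%).  The CYP2C19 phenotype is tested as a single
2-degree-of-freedom block (both non-reference multipliers together).

Every step is logged with the candidate, its OFV difference and the
decision, so a selection run can be audited or replayed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimation import (
    AGE_ON_CL,
    PHENOTYPE_ON_CL,
    CovariateTerm,
    FitConfig,
    FitResult,
    PKDataset,
    fit_foce,
)

logger = logging.getLogger("escipk")

#: chi-square critical values used in the published analysis
FORWARD_THRESHOLD = 6.63  # p < 0.01, 1 df
BACKWARD_THRESHOLD = 10.83  # p < 0.001, 1 df

#: Candidate covariates are specified with the same term type the
#: estimation module fits; re-export under the search-centric name.
CandidateCovariate = CovariateTerm


@dataclass
class SearchStep:
    phase: str  # 'forward' | 'backward'
    candidate: str
    delta_ofv: float
    df: int
    decision: str  # 'added' | 'removed' | 'rejected' | 'kept' | 'skipped'


@dataclass
class CovariateSearchResult:
    steps: list[SearchStep]
    included: tuple[CandidateCovariate, ...]
    final_fit: FitResult
    base_ofv: float

    def step_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "phase": s.phase,
                    "candidate": s.candidate,
                    "delta_ofv": s.delta_ofv,
                    "df": s.df,
                    "decision": s.decision,
                }
                for s in self.steps
            ]
        )

    def write_step_log(self, path) -> None:
        self.step_table().to_csv(path, sep="\t", index=False)


def _fit_with(dataset, covariates, config, init, init_extra=None):
    cfg = config.with_covariates(covariates)
    return fit_foce(dataset, init=init, config=cfg, init_extra=init_extra)


def _warm_extra(fit: FitResult) -> dict:
    return {k.split(":", 1)[1]: v for k, v in fit.extra_coefficients.items()}


def evaluate_candidate(
    dataset: PKDataset,
    base_fit: FitResult,
    candidate: CandidateCovariate,
    config: Optional[FitConfig] = None,
):
    """OFV drop from adding ``candidate`` to the model behind ``base_fit``.

    Both models are fitted to convergence; the enlarged fit is
    warm-started from the base estimates with a null candidate effect.
    Returns ``(delta_ofv, df, fit)``; a failed candidate fit returns
    ``(nan, df, None)`` and is skipped by the searches.
    """
    config = config or base_fit.config
    covs = tuple(base_fit.config.covariates) + (candidate,)
    try:
        fit = _fit_with(dataset, covs, config, base_fit.estimates, _warm_extra(base_fit))
    except Exception as exc:  # fit blow-up: candidate unusable, not fatal
        logger.warning("candidate %s skipped: %s", candidate.key, exc)
        return float("nan"), candidate.df, None
    if not fit.converged:
        logger.warning("candidate %s skipped: fit did not converge", candidate.key)
        return float("nan"), candidate.df, None
    return base_fit.ofv - fit.ofv, candidate.df, fit


def forward_search(
    dataset: PKDataset,
    base_fit: FitResult,
    candidates: Sequence[CandidateCovariate],
    threshold_fwd: float = FORWARD_THRESHOLD,
    config: Optional[FitConfig] = None,
) -> CovariateSearchResult:
    """Greedy forward inclusion from the model behind ``base_fit``.

    Ties on delta-OFV break lexicographically by candidate key, so the
    search is deterministic given the dataset.
    """
    config = config or base_fit.config
    steps: list[SearchStep] = []
    current = base_fit
    remaining = sorted(candidates, key=lambda c: c.key)
    included: list[CandidateCovariate] = []
    while remaining:
        results = []
        for cand in remaining:
            d, df, fit = evaluate_candidate(dataset, current, cand, config)
            if fit is None:
                steps.append(SearchStep("forward", cand.key, d, df, "skipped"))
            else:
                results.append((d, cand, fit))
        if not results:
            break
        # largest drop wins; lexicographic tie-break via the stable sort
        results.sort(key=lambda t: (-t[0], t[1].key))
        best_d, best_cand, best_fit = results[0]
        if not (best_d > threshold_fwd):
            for d, cand, _ in results:
                steps.append(SearchStep("forward", cand.key, d, cand.df, "rejected"))
            break
        for d, cand, _ in results:
            if cand is best_cand:
                steps.append(SearchStep("forward", cand.key, d, cand.df, "added"))
            else:
                steps.append(SearchStep("forward", cand.key, d, cand.df, "rejected"))
        included.append(best_cand)
        current = best_fit
        remaining = [c for c in remaining if c is not best_cand]
    return CovariateSearchResult(
        steps=steps, included=tuple(included), final_fit=current, base_ofv=base_fit.ofv
    )


def backward_elimination(
    dataset: PKDataset,
    full_fit: FitResult,
    threshold_bwd: float = BACKWARD_THRESHOLD,
    removable: Optional[Sequence[CandidateCovariate]] = None,
    config: Optional[FitConfig] = None,
) -> CovariateSearchResult:
    """Greedy backward elimination from the model behind ``full_fit``.

    Each round refits every sub-model with one covariate removed and
    drops the one whose removal raises the OFV the least, while that
    rise stays below ``threshold_bwd``.  Covariates surviving the search
    each raise the OFV by at least the threshold on removal.
    """
    config = config or full_fit.config
    steps: list[SearchStep] = []
    current = full_fit
    included = list(removable if removable is not None else full_fit.config.covariates)
    while included:
        results = []
        for cand in sorted(included, key=lambda c: c.key):
            covs = tuple(c for c in current.config.covariates if c is not cand)
            try:
                fit = _fit_with(dataset, covs, config, current.estimates, _warm_extra(current))
            except Exception as exc:
                logger.warning("removal of %s failed: %s", cand.key, exc)
                continue
            if not fit.converged:
                logger.warning("removal of %s skipped: no convergence", cand.key)
                continue
            rise = fit.ofv - current.ofv
            results.append((rise, cand, fit))
        if not results:
            break
        results.sort(key=lambda t: (t[0], t[1].key))
        rise, cand, fit = results[0]
        if rise >= threshold_bwd:
            for r, c, _ in results:
                steps.append(SearchStep("backward", c.key, r, c.df, "kept"))
            break
        steps.append(SearchStep("backward", cand.key, rise, cand.df, "removed"))
        included = [c for c in included if c is not cand]
        current = fit
    return CovariateSearchResult(
        steps=steps, included=tuple(included), final_fit=current, base_ofv=full_fit.ofv
    )


def stepwise_search(
    dataset: PKDataset,
    candidates: Sequence[CandidateCovariate],
    config: Optional[FitConfig] = None,
    init=None,
    threshold_fwd: float = FORWARD_THRESHOLD,
    threshold_bwd: float = BACKWARD_THRESHOLD,
) -> CovariateSearchResult:
    """Full forward-inclusion / backward-elimination covariate search.

    Starts from the covariate-free base model, runs the forward pass
    over ``candidates`` at ``threshold_fwd``, then backward elimination
    of the included set at ``threshold_bwd``.
    """
    config = (config or FitConfig()).with_covariates(())
    base_fit = fit_foce(dataset, init=init, config=config)
    fwd = forward_search(dataset, base_fit, candidates, threshold_fwd, config)
    bwd = backward_elimination(
        dataset, fwd.final_fit, threshold_bwd, removable=fwd.included, config=config
    )
    return CovariateSearchResult(
        steps=fwd.steps + bwd.steps,
        included=bwd.included,
        final_fit=bwd.final_fit,
        base_ofv=base_fit.ofv,
    )


#: Default candidate set mirroring the study's screened covariates: the
#: two true effects (age, CYP2C19 phenotype on CL) plus null decoys.
def default_candidates(include_decoys: bool = True) -> tuple[CandidateCovariate, ...]:
    cands = [AGE_ON_CL, PHENOTYPE_ON_CL]
    if include_decoys:
        cands += [
            CandidateCovariate("cl", "SEX", "categorical"),
            CandidateCovariate("cl", "WT", "continuous"),
            CandidateCovariate("cl", "ALT", "continuous"),
            CandidateCovariate("v", "WT", "continuous"),
        ]
    return tuple(cands)
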