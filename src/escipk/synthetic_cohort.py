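"""Virtual study cohorts with the statistical structure of the TDM study.

The real therapeutic-drug-monitoring dataset (106 psychiatric inpatients,
337 escitalopram serum concentrations) is not public; this module
generates cohorts that reproduce its reported structure so the
estimation, covariate-selection and validation machinery can be
exercised end to end:

* 106 subjects, ages spanning 12-83 years (median ~45), ~56% male;
* CYP2C19 diplotype frequencies *1/*1 44.34%, *1/*2 45.28%, *1/*3
  0.94%, *2/*2 6.60%, *2/*3 2.84% (implying EM 44.3% / IM 46.2% /
  PM 9.4%);
* daily doses 5-30 mg (median 10) over qd and bid regimens;
* sparse, trough-dominated sampling targeting ~337 observations in
  total (mean just over 3 per subject);
* concentrations simulated from the population model with log-normal
  inter-individual variability and proportional residual error, and an
  assay lower limit of quantification of 3 ng/ml.

Liver/kidney laboratory values and sex are generated with *no* effect on
the kinetics: they serve as null decoys for covariate-selection
specificity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimation import Observation, PKDataset, SubjectRecord
from .pk_model import (
    DoseEvent,
    PopulationParameters,
    Subject,
    phenotype_from_genotype,
)

logger = logging.getLogger("escipk")

#: Published CYP2C19 diplotype frequencies in the study population.
GENOTYPE_FREQUENCIES = {
    "*1/*1": 0.4434,
    "*1/*2": 0.4528,
    "*1/*3": 0.0094,
    "*2/*2": 0.0660,
    "*2/*3": 0.0284,
}

#: (dose per administration mg, interval h, label, probability).  Daily
#: doses span 5-30 mg with median 10, dominated by the 10 mg qd standard
#: regimen; bid variants mirror the regimens used clinically.
DEFAULT_REGIMEN_MIX = (
    (5.0, 24.0, "5 mg qd", 0.17),
    (10.0, 24.0, "10 mg qd", 0.40),
    (15.0, 24.0, "15 mg qd", 0.12),
    (20.0, 24.0, "20 mg qd", 0.13),
    (5.0, 12.0, "5 mg bid", 0.08),
    (10.0, 12.0, "10 mg bid", 0.07),
    (15.0, 12.0, "15 mg bid", 0.03),
)

LLOQ = 3.0  # ng/ml, assay lower limit of quantification


@dataclass
class CohortConfig:
    """Design of a synthetic cohort; defaults emulate the study."""

    n_subjects: int = 106
    age_min: float = 12.0
    age_median: float = 45.0
    age_max: float = 83.0
    male_fraction: float = 0.5566
    genotype_frequencies: dict = field(default_factory=lambda: dict(GENOTYPE_FREQUENCIES))
    regimen_mix: tuple = DEFAULT_REGIMEN_MIX
    target_observations: int = 337
    #: dosing days simulated before/while sampling
    n_days: int = 21
    #: samples drawn no earlier than this many dosing intervals after start
    min_intervals: int = 5
    #: fraction of random post-dose (non-trough) sampling times, for mild
    #: volume identifiability
    postdose_fraction: float = 0.10
    lloq: float = LLOQ

    def __post_init__(self) -> None:
        total = sum(self.genotype_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"genotype frequencies must sum to 1 (got {total})")
        if any(f < 0 for f in self.genotype_frequencies.values()):
            raise ValueError("genotype frequencies must be non-negative")


@dataclass
class Cohort:
    subjects: list[Subject]
    regimens: list[tuple]  # (dose mg, tau h, label) per subject
    config: CohortConfig


def sample_genotypes(n: int, frequencies: Optional[dict] = None, seed=None) -> list[str]:
    """Multinomial draw of CYP2C19 diplotypes."""
    frequencies = frequencies or GENOTYPE_FREQUENCIES
    total = sum(frequencies.values())
    if abs(total - 1.0) > 1e-6 or any(f < 0 for f in frequencies.values()):
        raise ValueError("frequencies must form a simplex")
    rng = np.random.default_rng(seed)
    names = list(frequencies)
    probs = np.array([frequencies[g] for g in names])
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


def allele_frequencies(genotype_counts: dict) -> dict:
    """Per-allele counts and percentages from diplotype counts.

    Each subject carries two alleles; the allele count is twice the
    homozygote count plus every heterozygote appearance, and percentages
    are over 2N chromosomes.
    """
    if not genotype_counts or all(c == 0 for c in genotype_counts.values()):
        raise ValueError("genotype counts are all zero")
    counts: dict[str, int] = {}
    n_subjects = 0
    for geno, c in genotype_counts.items():
        a, b = geno.split("/")
        counts[a] = counts.get(a, 0) + c
        counts[b] = counts.get(b, 0) + c
        n_subjects += c
    total = 2 * n_subjects
    return {
        allele: {"count": cnt, "percent": 100.0 * cnt / total}
        for allele, cnt in sorted(counts.items())
    }


def _sample_labs(rng: np.random.Generator) -> dict:
    """Null-effect liver/kidney labs with study-like medians and spread."""
    return {
        "ALT": float(np.exp(rng.normal(np.log(17.0), 0.6))),  # U/L
        "MAST": float(np.exp(rng.normal(np.log(4.3), 0.45))),  # U/L
        "TBIL": float(np.exp(rng.normal(np.log(9.4), 0.4))),  # mg/dl
        "ALB": float(rng.normal(40.4, 4.0)),
        "UREA": float(np.exp(rng.normal(np.log(4.0), 0.35))),
        "SCR": float(rng.normal(67.0, 18.0)),
    }


def generate_cohort(config: Optional[CohortConfig] = None, seed=None) -> Cohort:
    """Sample subjects (ages, sexes, genotypes, labs) and assign regimens."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    genotypes = sample_genotypes(
        config.n_subjects, config.genotype_frequencies, seed=rng.integers(2**31)
    )
    # equal-probability mixture of uniforms below/above the median: the
    # published cohort summaries (median 45, range 12-83) pin location
    # and support, and this dispersion carries the age information the
    # study's covariate analysis reports
    low = rng.random(config.n_subjects) < 0.5
    ages = np.where(
        low,
        rng.uniform(config.age_min, config.age_median, config.n_subjects),
        rng.uniform(config.age_median, config.age_max, config.n_subjects),
    )
    sexes = np.where(rng.random(config.n_subjects) < config.male_fraction, "male", "female")
    probs = np.array([r[3] for r in config.regimen_mix])
    probs = probs / probs.sum()
    reg_idx = rng.choice(len(config.regimen_mix), size=config.n_subjects, p=probs)

    subjects, regimens = [], []
    for i in range(config.n_subjects):
        weight = float(np.clip(rng.normal(61.0, 11.0), 37.0, 97.0))
        height = float(np.clip(rng.normal(165.0, 7.0), 150.0, 180.0))
        subjects.append(
            Subject(
                id=f"S{i + 1:03d}",
                age=float(ages[i]),
                sex=str(sexes[i]),
                weight=weight,
                height=height,
                genotype=genotypes[i],
                labs=_sample_labs(rng),
            )
        )
        dose, tau, label, _ = config.regimen_mix[reg_idx[i]]
        regimens.append((dose, tau, label))
    return Cohort(subjects=subjects, regimens=regimens, config=config)


def simulate_dataset(
    cohort: Cohort,
    truth: Optional[PopulationParameters] = None,
    seed=None,
    return_etas: bool = False,
):
    """Simulate concentrations for a cohort under the population model.

    Per subject: eta ~ N(0, Omega); trough-dominated sampling times
    (uniform in the last 2 h of a dosing interval, after at least
    ``min_intervals`` intervals, with a small admixture of random
    post-dose times); observed Y = f * (1 + eps), eps ~ N(0,
    sigma2_prop), plus additive noise when sigma2_add > 0.  Records
    below the LLOQ are flagged BLQ.
    """
    truth = truth or PopulationParameters()
    config = cohort.config
    rng = np.random.default_rng(seed)
    n = len(cohort.subjects)
    mean_obs = config.target_observations / n

    etas = np.stack(
        [
            rng.normal(0.0, np.sqrt(truth.omega2_cl), n),
            rng.normal(0.0, np.sqrt(truth.omega2_v), n),
        ],
        axis=1,
    )

    records = []
    for i, (subject, (dose, tau, label)) in enumerate(zip(cohort.subjects, cohort.regimens)):
        n_doses = int(round(config.n_days * 24.0 / tau))
        doses = [DoseEvent(time=k * tau, amount=dose) for k in range(n_doses)]
        # shifted-Poisson observation count, mean ~ target/n
        n_obs = 1 + rng.poisson(max(mean_obs - 1.0, 0.0))
        times = []
        for _ in range(n_obs):
            k = int(rng.integers(config.min_intervals, n_doses))
            if rng.random() < config.postdose_fraction:
                t = doses[k].time + rng.uniform(0.5, tau)
            else:
                t = doses[k].time + tau - rng.uniform(0.0, 2.0)
            times.append(t)
        times = sorted(times)

        from .pk_model import individual_parameters

        ind = individual_parameters(truth, subject, etas[i, 0], etas[i, 1])
        observations = []
        for t in times:
            from .pk_model import concentration_profile

            f = float(concentration_profile(doses, [t], ind.cl_i, ind.v_i, truth.ka)[0])
            yval = f * (1.0 + rng.normal(0.0, np.sqrt(truth.sigma2_prop)))
            if truth.sigma2_add > 0:
                yval += rng.normal(0.0, np.sqrt(truth.sigma2_add))
            yval = max(yval, 0.0)
            observations.append(Observation(time=t, conc=yval, blq=yval < config.lloq))
        # guarantee the dataset invariant of >=1 quantifiable observation
        if all(o.blq for o in observations):
            observations[-1].blq = False
            observations[-1].conc = max(observations[-1].conc, config.lloq)
            logger.info("subject %s: all simulated records BLQ; kept last", subject.id)
        records.append(SubjectRecord(subject=subject, doses=doses, observations=observations))

    dataset = PKDataset(records)
    n_blq = dataset.n_blq
    if n_blq:
        logger.info("simulated dataset: %d BLQ record(s) below %.1f ng/ml", n_blq, config.lloq)
    if return_etas:
        return dataset, etas
    return dataset


def generate_study(
    seed=None,
    truth: Optional[PopulationParameters] = None,
    config: Optional[CohortConfig] = None,
):
    """One-call study-scale synthetic dataset (cohort + concentrations)."""
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(config, seed=rng.integers(2**31))
    return simulate_dataset(cohort, truth=truth, seed=rng.integers(2**31))
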