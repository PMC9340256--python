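"""One-compartment oral PK model with covariate and random-effect structure.

The structural model is a one-compartment disposition with first-order
absorption and first-order elimination, parameterized in apparent oral
clearance CL/F (L/h), apparent volume of distribution V/F (L) and the
absorption rate constant ka (1/h).  Because bioavailability F is not
identifiable from oral data alone, all parameters are apparent (divided
by F).

Individual parameters are log-normally distributed around a
covariate-adjusted typical value,

    CL_i = TVCL * g_pheno(CYP2C19_i) * g_age(age_i) * exp(eta_CL),
    V_i  = TVV * exp(eta_V),

with ``g_pheno`` a phenotype multiplier (extensive metabolizers are the
reference, intermediate and poor metabolizers have multipliers below 1)
and ``g_age`` a linear calibrator centred at the cohort median age,

    g_age(age) = 1 - theta_age * (age - age_center),

so a positive ``theta_age`` encodes clearance declining with age.  All
multipliers are clamped to a configurable positive floor so extreme
covariate values can never produce a non-positive parameter.

Doses are in mg, volumes in L and concentrations in ng/ml; the mg/L ->
ng/ml unit factor of 1000 is applied exactly once, inside the structural
model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("escipk")

#: mg/L -> ng/ml (ug/L) conversion, applied once in the structural model.
CONC_SCALE = 1000.0

#: Multiplier floor for linear covariate calibrators (see module docstring).
MULTIPLIER_FLOOR = 0.05

#: Relative ka ~= ke threshold below which the equal-rate limit form is used.
EQUAL_RATE_RTOL = 1e-9

#: CYP2C19 diplotype -> predicted metabolizer phenotype.
PHENOTYPE_FROM_GENOTYPE = {
    "*1/*1": "EM",
    "*1/*2": "IM",
    "*1/*3": "IM",
    "*2/*2": "PM",
    "*2/*3": "PM",
}

PHENOTYPES = ("EM", "IM", "PM")


def phenotype_from_genotype(genotype: str) -> str:
    """Map a CYP2C19 diplotype over {*1, *2, *3} to EM / IM / PM."""
    try:
        return PHENOTYPE_FROM_GENOTYPE[genotype]
    except KeyError:
        raise ValueError(
            f"unknown CYP2C19 genotype {genotype!r}; expected one of "
            f"{sorted(PHENOTYPE_FROM_GENOTYPE)}"
        ) from None


@dataclass
class PopulationParameters:
    """Population (typical) parameters, covariate calibrators and variances.

    Defaults are the final published estimates for escitalopram in adult
    psychiatric patients (CL/F 16.3 L/h, V/F 815 L, ka fixed at 0.6 1/h,
    age calibrator 0.0077 per year centred at 45 y, IM and PM clearance
    multipliers 0.847 and 0.479, IIV variances 0.0877 / 0.235 and
    proportional residual variance 0.0287).
    """

    tvcl: float = 16.3
    tvv: float = 815.0
    ka: float = 0.6
    theta_age: float = 0.0077
    theta_im: float = 0.847
    theta_pm: float = 0.479
    omega2_cl: float = 0.0877
    omega2_v: float = 0.235
    sigma2_prop: float = 0.0287
    sigma2_add: float = 0.0
    age_center: float = 45.0
    #: -1 encodes g_age = 1 - theta_age*(age - center) (clearance decreasing
    #: in age for positive theta_age); +1 flips the convention.
    age_sign: int = -1

    def __post_init__(self) -> None:
        if not (self.tvcl > 0 and self.tvv > 0 and self.ka > 0):
            raise ValueError("tvcl, tvv and ka must all be positive")
        if not (self.theta_im > 0 and self.theta_pm > 0):
            raise ValueError("phenotype multipliers must be positive")
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("IIV variances must be non-negative")
        if self.sigma2_prop < 0 or self.sigma2_add < 0:
            raise ValueError("residual variances must be non-negative")
        if self.age_sign not in (-1, 1):
            raise ValueError("age_sign must be -1 or +1")

    def phenotype_multiplier(self, phenotype: str) -> float:
        if phenotype == "EM":
            return 1.0
        if phenotype == "IM":
            return self.theta_im
        if phenotype == "PM":
            return self.theta_pm
        raise ValueError(f"unknown phenotype {phenotype!r}; expected EM/IM/PM")

    def age_multiplier(self, age) -> np.ndarray | float:
        """Linear age calibrator, clamped at MULTIPLIER_FLOOR."""
        g = 1.0 + self.age_sign * self.theta_age * (np.asarray(age, float) - self.age_center)
        clipped = np.clip(g, MULTIPLIER_FLOOR, None)
        if np.any(g < MULTIPLIER_FLOOR):
            logger.warning(
                "age multiplier clamped to floor %.3g for %d value(s)",
                MULTIPLIER_FLOOR,
                int(np.sum(g < MULTIPLIER_FLOOR)),
            )
        if np.ndim(age) == 0:
            return float(clipped)
        return clipped

    def replace(self, **kwargs) -> "PopulationParameters":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class IndividualParameters:
    """Subject-level parameters at given random effects."""

    eta_cl: float
    eta_v: float
    cl_i: float
    v_i: float


@dataclass
class Subject:
    """Covariates for one patient.

    ``phenotype`` is derived from ``genotype`` when omitted; supplying
    both checks consistency against the fixed diplotype->phenotype map.
    """

    id: str
    age: float
    sex: str = "male"
    weight: Optional[float] = None
    height: Optional[float] = None
    genotype: Optional[str] = None
    phenotype: Optional[str] = None
    labs: dict = field(default_factory=dict)
    comedication: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"subject {self.id}: age must be positive")
        if self.genotype is not None:
            derived = phenotype_from_genotype(self.genotype)
            if self.phenotype is None:
                self.phenotype = derived
            elif self.phenotype != derived:
                raise ValueError(
                    f"subject {self.id}: phenotype {self.phenotype} inconsistent "
                    f"with genotype {self.genotype} (expected {derived})"
                )
        if self.phenotype is not None and self.phenotype not in PHENOTYPES:
            raise ValueError(f"subject {self.id}: unknown phenotype {self.phenotype!r}")

    def covariate(self, name: str):
        """Look up a covariate by column-style name (AGE, SEX, WT, ... or a lab)."""
        key = name.upper()
        if key == "AGE":
            return self.age
        if key == "SEX":
            return 0.0 if self.sex == "male" else 1.0
        if key == "WT":
            return self.weight
        if key == "HT":
            return self.height
        if key in self.labs:
            return self.labs[key]
        if key in self.comedication:
            return float(bool(self.comedication[key]))
        raise KeyError(f"subject {self.id} has no covariate {name!r}")


@dataclass
class DoseEvent:
    """One oral dose: time in hours since the subject's first dose, amount in mg."""

    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")


def individual_parameters(
    pop: PopulationParameters,
    subject: Subject,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """Covariate-adjusted individual CL/F and V/F at given random effects."""
    if subject.phenotype is None:
        raise ValueError(f"subject {subject.id} has no phenotype/genotype")
    g_pheno = pop.phenotype_multiplier(subject.phenotype)
    g_age = pop.age_multiplier(subject.age)
    cl_i = pop.tvcl * g_pheno * g_age * math.exp(eta_cl)
    v_i = pop.tvv * math.exp(eta_v)
    return IndividualParameters(eta_cl=eta_cl, eta_v=eta_v, cl_i=cl_i, v_i=v_i)


def single_dose_concentration(t, dose: float, cl: float, v: float, ka: float):
    """Concentration (ng/ml) at ``t`` hours after one oral dose of ``dose`` mg.

    Bateman form C(t) = (1000*D/V) * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))
    with ke = CL/V; the ka == ke removable singularity is evaluated by its
    analytic limit (1000*D/V) * ka * t * exp(-ka t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dose must be >= 0")
    if not (cl > 0 and v > 0 and ka > 0):
        raise ValueError("cl, v and ka must be positive")
    ke = cl / v
    if abs(ka - ke) < EQUAL_RATE_RTOL * ka:
        c = CONC_SCALE * dose / v * ka * t * np.exp(-ka * t)
    else:
        c = (
            CONC_SCALE
            * dose
            / v
            * ka
            / (ka - ke)
            * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    return c if c.ndim else float(c)


def concentration_profile(
    doses: Sequence[DoseEvent],
    times,
    cl: float,
    v: float,
    ka: float,
):
    """Multiple-dose concentrations by linear superposition of single doses.

    ``times`` are hours since the first dose; doses administered after a
    given time do not contribute to it.  An empty dose list yields zeros.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for d in doses:
        dt = times - d.time
        mask = dt >= 0
        if np.any(mask):
            out[mask] += single_dose_concentration(dt[mask], d.amount, cl, v, ka)
    return out


def steady_state_trough(dose: float, tau: float, cl: float, v: float, ka: float) -> float:
    """Steady-state pre-dose (trough) concentration for ``dose`` mg every ``tau`` h.

    Closed form from summing the geometric series of superposed doses:

        C_ss,min = (1000*D/V) * ka/(ka-ke)
                   * [exp(-ke*tau)/(1-exp(-ke*tau)) - exp(-ka*tau)/(1-exp(-ka*tau))]
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if tau <= 0:
        raise ValueError("dosing interval tau must be positive")
    if not (cl > 0 and v > 0 and ka > 0):
        raise ValueError("cl, v and ka must be positive")
    ke = cl / v
    if abs(ka - ke) < EQUAL_RATE_RTOL * ka:
        r = math.exp(-ka * tau)
        return CONC_SCALE * dose / v * ka * tau * r / (1.0 - r) ** 2
    re = math.exp(-ke * tau)
    ra = math.exp(-ka * tau)
    return (
        CONC_SCALE
        * dose
        / v
        * ka
        / (ka - ke)
        * (re / (1.0 - re) - ra / (1.0 - ra))
    )
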