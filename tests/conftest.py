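"""Shared fixtures: small deterministic datasets and one study-scale fit."""

import numpy as np
import pytest

from escipk import (
    CohortConfig,
    FitConfig,
    PopulationParameters,
    fit_foce,
    generate_study,
)

#: seed of the reference synthetic study used across the suite
STUDY_SEED = 1


@pytest.fixture(scope="session")
def truth():
    """Generating (published final-model) parameters."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def study_dataset(truth):
    """Study-scale synthetic dataset: 106 subjects, ~337 trough observations."""
    return generate_study(seed=STUDY_SEED, truth=truth)


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    """FOCE-I fit of the reference study from the neutral default start."""
    fit = fit_foce(study_dataset)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_dataset(truth):
    """A quick 12-subject dataset for estimation unit tests."""
    config = CohortConfig(n_subjects=12, target_observations=40)
    from escipk.synthetic_cohort import generate_cohort, simulate_dataset

    cohort = generate_cohort(config, seed=7)
    return simulate_dataset(cohort, truth=truth, seed=8)
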