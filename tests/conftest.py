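"""Shared fixtures: published model, synthetic cohorts and datasets."""

import numpy as np
import pytest

import daptopk as d


@pytest.fixture(scope="session")
def pm():
    """Published final population model (generating truth for simulations)."""
    return d.final_model()


def make_dataset(pm, n_subjects=46, cohort_seed=42, data_seed=43):
    spec = d.CohortSpec(n_subjects=n_subjects, seed=cohort_seed)
    cohort = d.generate_cohort(spec)
    return d.generate_dataset(cohort, d.DesignSpec(), pm, seed=data_seed, spec=spec)


@pytest.fixture(scope="session")
def study_dataset(pm):
    """One full-size synthetic study (46 subjects, ~157 observations)."""
    return make_dataset(pm)


@pytest.fixture(scope="session")
def tiny_dataset(pm):
    """A 3-subject dataset for quadrature-oracle and toy tests."""
    return make_dataset(pm, n_subjects=3, cohort_seed=7, data_seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
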