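"""Shared fixtures: small synthetic cohorts reused across the suite.

All cohorts are scaled down (few subjects, 15-s records) so the whole
suite runs on one CPU; the generative model and every pipeline stage are
identical to full-scale runs.
"""

import numpy as np
import pytest

from erpscreen import CohortSpec, generate_cohort
from erpscreen.features import extract_feature_tables


@pytest.fixture(scope="session")
def small_spec():
    """Effectful cohort: 6 subjects per group, 10-stimulus (15 s) runs."""
    return CohortSpec(n_per_group=6, n_stimuli=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return extract_feature_tables(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
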