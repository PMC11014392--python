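"""Shared fixtures: simulated cohorts and their feature tables.

The cohorts are expensive enough (hundreds of 10 s recordings) that they
are built once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from imuscore import SeverityParams, simulate_cohort
from imuscore.features import extract_cohort_features

#: Reference cohort dimensions: 33 patients + 12 controls, 6 tasks x 2
#: hands each, 32 contaminated recordings.
COHORT_KW = dict(n_pd=33, n_controls=12, dropout=32, seed=7)


@pytest.fixture(scope="session")
def cohort():
    """Well-separated severity cohort at the reference dimensions."""
    return simulate_cohort(**COHORT_KW)


@pytest.fixture(scope="session")
def feature_table(cohort):
    """Magnitude-variant feature table of the non-contaminated recordings."""
    return extract_cohort_features(cohort, variant="magnitude")


@pytest.fixture(scope="session")
def null_feature_table():
    """Feature table from a cohort whose scores carry no signal at all."""
    null = simulate_cohort(
        n_pd=33, n_controls=12, dropout=0, seed=5,
        severity=SeverityParams.fully_overlapping(),
    )
    return extract_cohort_features(null, variant="magnitude")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
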