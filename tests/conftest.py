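"""Shared fixtures: small synthetic cohorts and assembled datasets.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stroketriage import assembly
from stroketriage.cohort import CohortSpec, cohort_tables, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-episode cohort with the default label mixture."""
    return generate_cohort(CohortSpec(n_episodes=400), seed=101)


@pytest.fixture(scope="session")
def small_master(small_cohort):
    clinical, hemo, histories = cohort_tables(small_cohort)
    return assembly.merge_sources(clinical, hemo, histories)


@pytest.fixture(scope="session")
def lvo_matrix(small_master):
    """Feature matrix / target for the LVO task on the small cohort."""
    return assembly.build_task_matrix(small_master, "lvo")


@pytest.fixture(scope="session")
def ga_fixture():
    """8-variable dataset with two informative columns (2 and 5)."""
    rng = np.random.default_rng(123)
    X = rng.normal(size=(60, 8))
    y = (X[:, 2] + 0.6 * X[:, 5] + 0.5 * rng.normal(size=60) > 0).astype(int)
    return X, y


@pytest.fixture()
def leak_fixture():
    """One feature equals the label; the rest are noise."""
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, size=80)
    X = rng.normal(size=(80, 5))
    X[:, 3] = y
    return X, y
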