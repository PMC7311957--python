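"""Shared fixtures: small synthetic datasets and quick fits.

Everything is generated programmatically at fixed seeds; module/session
scope keeps the expensive SAEM fits to one execution per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from bevpkpd.cohort import CohortSpec, dense_plan, generate_cohort, simulate_dataset
from bevpkpd.models import pk_reference
from bevpkpd.saem import SAEMConfig, saem_fit


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_subjects=40, p_q2w=1.0), seed=61)


@pytest.fixture(scope="session")
def small_pk_dataset(small_cohort):
    ds, truth = simulate_dataset(small_cohort, pk_reference(), 62,
                                 plan=dense_plan(4, observables=(1,)))
    return ds, truth


@pytest.fixture(scope="session")
def small_pk_fit(small_pk_dataset):
    ds, _ = small_pk_dataset
    return saem_fit(ds, pk_reference(), SAEMConfig(k1=80, k2=30, seed=63))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
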