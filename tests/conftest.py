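"""Shared fixtures.

Heavy GLV simulation fixtures are session-scoped so that the
acceptance-level tests (headline errors, baseline comparison,
monotonicity) reuse the same cohorts instead of regenerating them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from knnbiome.cohort import Cohort
from knnbiome.glv import CohortSpec, generate_cohort

HEADLINE_KS = (1, 2, 5, 10)
HEADLINE_N_REALIZATIONS = 30
HEADLINE_N_TRAIN = 100
HEADLINE_N_TEST = 20


@pytest.fixture
def toy_cohort() -> Cohort:
    """Four hand-built samples over five species."""
    rows = np.array(
        [
            [0.5, 0.5, 0.0, 0.0, 0.0],
            [0.2, 0.3, 0.5, 0.0, 0.0],
            [0.0, 0.4, 0.0, 0.6, 0.0],
            [0.1, 0.1, 0.3, 0.2, 0.3],
        ]
    )
    return Cohort(rows)


@pytest.fixture(scope="session")
def glv_cohort_small() -> Cohort:
    """One quick N=10 GLV cohort shared by light-weight tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(
            CohortSpec(n_species=10, n_samples=60, sigma=0.6, seed=424242)
        )


def _split(cohort: Cohort, n_train: int):
    train = cohort.subset(np.arange(n_train))
    test = cohort.subset(np.arange(n_train, cohort.n_samples))
    return train, test


@pytest.fixture(scope="session")
def headline_cohorts():
    """GLV train/test cohorts at the headline conditions.

    For each pool size N in {10, 20, 40}: ``HEADLINE_N_REALIZATIONS``
    independent cohorts of 100 training + 20 test steady states at
    sigma = 0.6 (influence weighting).  Returned as
    {N: [(train, test), ...]}.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n_species in (10, 20, 40):
            seeds = np.random.SeedSequence(20240 + n_species).spawn(
                HEADLINE_N_REALIZATIONS
            )
            pairs = []
            for s in seeds:
                cohort = generate_cohort(
                    CohortSpec(
                        n_species=n_species,
                        n_samples=HEADLINE_N_TRAIN + HEADLINE_N_TEST,
                        sigma=0.6,
                        seed=int(np.random.default_rng(s).integers(2**31 - 1)),
                    )
                )
                pairs.append(_split(cohort, HEADLINE_N_TRAIN))
            out[n_species] = pairs
    return out


@pytest.fixture(scope="session")
def headline_knn_errors(headline_cohorts):
    """Per-realization kNN error curves and null errors at the headline grid.

    {N: {"per_k": array (reals, n_ks) of mean test error per k,
         "null": array (reals,)}} with ks = HEADLINE_KS.
    """
    from knnbiome.knn import AssemblageKNN

    out = {}
    for n_species, pairs in headline_cohorts.items():
        per_k = []
        null = []
        for train, test in pairs:
            ev = AssemblageKNN(train).evaluate(test, HEADLINE_KS)
            per_k.append(ev.errors)
            null.append(ev.null_error)
        out[n_species] = {"per_k": np.array(per_k), "null": np.array(null)}
    return out
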