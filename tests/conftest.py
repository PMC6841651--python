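import numpy as np
import pytest

import phrex
from phrex.testing import random_params, random_record  # re-export for tests

__all__ = ["random_params", "random_record"]


@pytest.fixture(scope="session")
def ref():
    """Shipped fitted parameter set (revised model) and its day convention."""
    params, days_per_year = phrex.reference_params()
    return params, days_per_year


@pytest.fixture(scope="session")
def ref_params(ref):
    return ref[0]


@pytest.fixture(scope="session")
def full_params(ref_params):
    """Same rates but with nu1, nu2, rho1 free (full 16-parameter model)."""
    return ref_params.with_mask(frozenset()).with_values(
        nu1=0.4, nu2=0.2, rho1=0.3)


@pytest.fixture(scope="session")
def cohort_5k(ref_params):
    """One seeded synthetic cohort of 5,000 patients at the reference fit."""
    cfg = phrex.CohortConfig(params=ref_params, n=5000, seed=20260929)
    return phrex.simulate_cohort(cfg)


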