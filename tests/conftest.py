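import numpy as np
import pytest

from sigrank.core_io import SignedSignature
from sigrank.synthetic_data import (
    CohortSimSpec,
    TumorSimSpec,
    simulate_cohort,
    simulate_tumor_matrix,
)


@pytest.fixture(scope="session")
def tumor_fixture():
    """Default seeded two-group tumor matrix with 7+17 planted genes."""
    return simulate_tumor_matrix(TumorSimSpec(rng_seed=7))


@pytest.fixture(scope="session")
def cohort_fixture():
    """Seeded cohort with the planted hazard ratio of 2.24 (n=400)."""
    return simulate_cohort(CohortSimSpec(rng_seed=11))


@pytest.fixture(scope="session")
def null_cohort_fixture():
    """Cohort whose survival is independent of expression (true HR = 1)."""
    return simulate_cohort(CohortSimSpec(n_patients=100, true_hr=1.0, rng_seed=5))


@pytest.fixture(scope="session")
def planted_signature():
    return SignedSignature(
        "planted", {f"sig_up{i}" for i in range(7)}, {f"sig_dn{i}" for i in range(17)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
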