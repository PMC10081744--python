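import numpy as np
import pytest

from mfisplit.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def balanced_cohort():
    """Small cohort with near-uniform destination marginals (fast training)."""
    return generate_cohort(CohortSpec.balanced(n_records=3000, seed=42))


@pytest.fixture(scope="session")
def population_cohort():
    """Mid-size cohort with the home-heavy population marginals."""
    return generate_cohort(CohortSpec.population(n_records=20_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def all_false_flags():
    from mfisplit.frailty import INDICATORS

    return {name: False for name in INDICATORS}
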