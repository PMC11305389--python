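import numpy as np
import pytest

from spinemem import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """16-case single-region cohort shared by read-only tests."""
    return generate_cohort(CohortParams(seed=42, n_cases=16,
                                        regions=("BA37",)))


@pytest.fixture(scope="session")
def light_full_cohort():
    """Default-sized cohort (128 cases) with a light spine load.

    Case-level structure (ages, sex, pathology, missingness) is at the
    default study scale; one neuron per case keeps spine generation cheap
    for tests that only exercise the case tables.
    """
    return generate_cohort(CohortParams(seed=7, regions=("BA37",),
                                        neurons_per_case=(1, 1)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
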