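import numpy as np
import pytest

from cogaging.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-participant cohort shared by read-only tests."""
    cfg = CohortConfig(n_survivors=60, n_controls=40, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
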