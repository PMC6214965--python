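import numpy as np
import pytest

from spinepath import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticCohortSpec(seed=20181102)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def straight_spine_coords(height: float = 425.0, n: int = 17) -> np.ndarray:
    """A perfectly straight vertical spine (x = y = 0)."""
    z = np.linspace(height, 0.0, n)
    return np.column_stack([np.zeros(n), np.zeros(n), z])
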