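import numpy as np
import pytest

from aslgpc.synthetic import CohortSpec, simulate_cohort
from aslgpc.volume import ellipsoid_mask


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Desk-scale cohort: 4 subjects, 2 scans/session, 10x12x10 grid."""
    return CohortSpec(
        n_subjects=4,
        n_scans_per_session=2,
        grid_shape=(10, 12, 10),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_mask(tiny_spec):
    return ellipsoid_mask(tiny_spec.grid_shape)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
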