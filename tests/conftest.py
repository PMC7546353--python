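import numpy as np
import pytest

from impactkin import (
    ImpactGenConfig,
    LowRankGenConfig,
    generate_impact_dataset,
    generate_lowrank_matrix,
)
from impactkin.metrics import BAMParams

# Plausible-scale synthetic lumped brain-skull parameters for testing: a
# ~15 Hz natural frequency and light damping, the regime reported for
# brain-skull relative rotation. Values are test fixtures, not published
# calibrations.
TEST_BAM_PARAMS = BAMParams(
    inertia=(0.016, 0.016, 0.016),
    stiffness=(142.0, 142.0, 142.0),
    damping=(0.9, 0.9, 0.9),
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic impacts for cheap structural tests."""
    return generate_impact_dataset(ImpactGenConfig(n_impacts=60, seed=42))


@pytest.fixture(scope="session")
def lowrank_matrix():
    """Exactly-rank-3 matrix with known singular values (5, 2, 1)."""
    return generate_lowrank_matrix(
        LowRankGenConfig(k_true=3, m=100, n=50, singular_values=(5, 2, 1), seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
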