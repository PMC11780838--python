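import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motormod as mm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Fixed seed for every seeded fixture in the suite.
SEED = 1


@pytest.fixture(scope="session")
def subset_truth() -> mm.GroundTruth:
    """Planted 3-module subset-8 ground truth at default noise (sd 0.02)."""
    return mm.make_ground_truth(mm.SUBSET_8, seed=SEED)


@pytest.fixture(scope="session")
def subset_truth_noiseless() -> mm.GroundTruth:
    return mm.make_ground_truth(mm.SUBSET_8, noise_sd=0.0, seed=SEED)


@pytest.fixture(scope="session")
def full_truth() -> mm.GroundTruth:
    """Planted 4-module full-set ground truth at default noise."""
    return mm.make_ground_truth(mm.FULL_43, seed=SEED)


@pytest.fixture(scope="session")
def ref_condition() -> mm.ConditionSpec:
    return mm.reference_condition("right", "subset_8")


@pytest.fixture(scope="session")
def ref_E(subset_truth, ref_condition) -> np.ndarray:
    return mm.synthesize_activations(subset_truth, ref_condition)


@pytest.fixture(scope="session")
def ref_extraction(ref_E):
    return mm.nmf_decompose(ref_E, 3, seed=0, replicates=10)


@pytest.fixture(scope="session")
def ref_vaf_curve(ref_E):
    """Best-of-10-replicates VAF curve for the reference activations."""
    return mm.vaf_curve(ref_E, n_max=8, replicates=10, seed=0)
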