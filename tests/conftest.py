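import numpy as np
import pytest

import vertiseg as vs

# nominal inter-center spacing statistics shared across the suite (mm)
GAP_MEAN = 30.0
GAP_SD = 2.0


def synthetic_training_centers(n_scans: int = 40, n_centers: int = 18, seed: int = 0):
    """Ordered body-center lists emulating a training set of full spines."""
    rng = np.random.default_rng(seed)
    lists = []
    for _ in range(n_scans):
        z = np.cumsum(np.r_[0.0, rng.normal(GAP_MEAN, GAP_SD, n_centers - 1)])
        lists.append(np.c_[z, np.zeros(n_centers), np.zeros(n_centers)])
    return lists


@pytest.fixture(scope="session")
def distance_model() -> vs.DistanceModel:
    return vs.fit_distance_model(synthetic_training_centers())


@pytest.fixture(scope="session")
def small_phantom():
    """A 5-vertebra phantom with ground truth (volume, labels, centers)."""
    spec = vs.PhantomSpec(n_vertebrae=5, seed=7)
    return vs.spine_phantom_with_centers(spec)
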