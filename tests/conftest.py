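import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (96 x 53, groups 38/58) plus symptoms."""
    from phenosom.simulate import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_z(default_cohort):
    from phenosom.preprocess import preprocess

    return preprocess(default_cohort[0])


@pytest.fixture(scope="session")
def two_blobs():
    """Two 10-sigma-separated Gaussian blobs in 5 dimensions (n = 60)."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(25, 5))
    b = rng.normal(10.0, 1.0, size=(35, 5))
    x = np.vstack([a, b])
    labels = np.r_[np.ones(25, dtype=int), np.full(35, 2, dtype=int)]
    return x, labels
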