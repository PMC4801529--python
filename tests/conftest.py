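import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bittertongue.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_dataset():
    """n=100 clean rank-one sensor dataset with its generating truth."""
    cfg = SyntheticConfig(n_samples=100, seed=5).without_contamination()
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def leverage_dataset():
    """n=100 with 15% bad-leverage contamination at magnitude 10."""
    cfg = SyntheticConfig(
        n_samples=100, seed=7, contamination=(("bad_leverage", 0.15, 10.0),)
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_regression():
    """Well-conditioned 30x5 Gaussian regression problem."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 5))
    beta = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
    y = X @ beta + 2.0 + 0.1 * rng.normal(size=30)
    return X, y, beta
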