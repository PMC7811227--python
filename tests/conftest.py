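import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-sample synthetic dataset shared by pipeline-level tests."""
    from rnalocmkl import GeneratorConfig, generate_dataset

    return generate_dataset(GeneratorConfig(n_samples=60, seed=7))
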