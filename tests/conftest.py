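import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codseg import SyntheticSpec, generate_dataset, generate_trial

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_syn():
    """Default synthetic V-cut trial (4 CODs, mild velocity noise)."""
    return generate_trial(SyntheticSpec())


@pytest.fixture(scope="session")
def clean_syn():
    """Noise-free synthetic trial."""
    return generate_trial(SyntheticSpec(velocity_noise_sd=0.0))


@pytest.fixture(scope="session")
def cohort_pooled():
    """Cohort-sized pooled dataset: 62 players x 2 tests x 2 repetitions."""
    return generate_dataset(62 * 2 * 2, seed=11, stratified=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
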