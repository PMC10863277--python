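import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete 8-class synthetic cohort for integration tests."""
    from episcore.synthetic import default_cohort_spec, generate_cohort

    spec = default_cohort_spec(n_normal=60, n_per_disorder=8, n_probes=300, seed=7)
    beta, samples = generate_cohort(spec)
    return spec, beta, samples
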