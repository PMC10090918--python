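import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220528)


@pytest.fixture
def default_cohort():
    """Study-scale synthetic cohort: 370 samples, 14 injected spikes."""
    from erykal import CohortConfig, generate_cohort, inject_spikes

    table = generate_cohort(CohortConfig(n=370, seed=11))
    return inject_spikes(table, 14, seed=12)
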