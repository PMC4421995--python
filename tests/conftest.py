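import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import decaydet as d

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """120-gene synthetic dataset; UTRs >= 20 nt so no gene is dropped."""
    config = d.GenomeConfig(n_genes=120, utr_len_range=(20, 100))
    return d.generate_dataset(config, seed=42)


@pytest.fixture(scope="session")
def ref_usage():
    return d.ReferenceUsage.from_sequences(d.generate_reference_set(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
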