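import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fixture():
    """A small synthetic dataset: 5 single-copy genes, 2 paralogue pairs,
    2 uncollapsed heterozygous loci, 30x depth."""
    from agtuner.synthetic import SyntheticConfig, generate_fixture

    config = SyntheticConfig(
        n_single=5, n_paralog_pairs=2, n_false_duplication_loci=2, depth=30.0, seed=7
    )
    return config, generate_fixture(config)
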