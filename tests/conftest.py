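import numpy as np
import pytest

from mosegcn import SyntheticSpec, generate_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, clearly separable synthetic dataset shared across tests."""
    spec = SyntheticSpec(
        n_samples=60,
        n_classes=3,
        feature_counts=(20, 15, 10),
        informative_per_omics=5,
        effect_size=4.0,
        labeled_fraction=0.3,
        seed=1,
    )
    return generate_multiomics(spec)
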