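import numpy as np
import pytest

from graddp.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Small phantom config: fast to generate, still anatomically layered."""
    return PhantomConfig(image_size=(64, 64), slices_per_subject=4, modality="t2", seed=7)


@pytest.fixture(scope="session")
def tiny_binary_cohort(tiny_config):
    return generate_dataset(tiny_config, n_subjects_per_class=3, task="binary")
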