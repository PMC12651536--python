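import numpy as np
import pytest

from efccnet import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small protocol used across tests: 2 x 6 x 1 x 5 = 60 epochs of 21 x 64."""
    return synthetic.SyntheticSpec(
        n_subjects=2,
        n_repetitions=1,
        epochs_per_recording=5,
        fs=64.0,
        band=(0.5, 28.0),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return synthetic.generate_dataset(tiny_spec)
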