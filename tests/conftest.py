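import numpy as np
import pytest

from tippingews import EWSNetConfig, TrainingConfig, build_dataset


@pytest.fixture(scope="session")
def small_dataset_w():
    """A small white-noise dataset shared by read-only tests."""
    return build_dataset("W", 10, seed=1234)


@pytest.fixture(scope="session")
def tiny_net_config():
    return EWSNetConfig(
        conv_filters=(4, 6, 4), conv_kernels=(8, 5, 3), lstm_units=6, fc_sizes=(8, 3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
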