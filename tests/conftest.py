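import numpy as np
import pytest

import dynergy as dg
from dynergy.model import extract_sequences
from dynergy.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def cheap_config(n_subjects=10, trials_per_subject=20, seed=7, **overrides):
    """Small, fast bundle: 8 channels @128 Hz, 12-s trials (5 windows)."""
    return SyntheticConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject,
        n_channels=8, fs=128.0, duration_s=12.0, seed=seed, **overrides)


@pytest.fixture(scope="session")
def cheap_bundle():
    """200 separable 2-class trials, cheap shape."""
    return generate_bundle(cheap_config(seed=7))


@pytest.fixture(scope="session")
def cheap_sequences(cheap_bundle):
    """seed17 window sequences for the cheap bundle (trials x 5 x 17)."""
    return extract_sequences(cheap_bundle, subset="seed17").values


def small_netspec(**overrides):
    """Reduced-size network spec for fast unit tests."""
    defaults = dict(input_size=17, seq_len=5, bilstm_units=16, lstm_units=8,
                    dense1=16, n_classes=2, epochs=10, seed=0)
    defaults.update(overrides)
    return dg.NetworkSpec(**defaults)
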