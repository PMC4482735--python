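import numpy as np
import pytest

from edmp import DictionarySpec


@pytest.fixture
def toy_spec():
    """Small dictionary for exhaustive/oracle comparisons (~700 atoms)."""
    return DictionarySpec(
        sampling_rate=256.0,
        window_length=256,
        freq_grid=(16.0, 32.0, 48.0, 64.0, 80.0),
        scale_grid=(0.02 ** 2, 0.05 ** 2),
        alpha_levels=(0.0, -1.0, 1.0),
        time_step=16,
    )


@pytest.fixture
def eeg_small_spec():
    """Reduced EEG-band dictionary used by the recovery experiments."""
    return DictionarySpec(
        sampling_rate=64.0,
        window_length=256,
        freq_grid=tuple(np.arange(2.0, 31.0, 1.0)),
        scale_grid=(0.25 ** 2, 0.5 ** 2, 1.0 ** 2),
        alpha_levels=(0.0, -1.0, 1.0, -3.0, 3.0),
        time_step=16,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
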