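import numpy as np
import pytest

from cosparse_eeg import signal_data as sd


@pytest.fixture(scope="session")
def small_spec():
    """Small but separable two-class spec used across integration tests."""
    return sd.SyntheticSpec(n_records_per_class=6, record_length=1150,
                            fs=173.61, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    records = sd.generate_synthetic(small_spec)
    return sd.segment_records(records, 6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
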