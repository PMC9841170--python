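import warnings

import numpy as np
import pytest

from ldsb_eeg import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_routine_warnings():
    """FNN caps and short-record band warnings are routine in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        yield


@pytest.fixture(scope="session")
def wake_recording():
    rec, truth = syn.generate_recording(syn.WAKE_PROFILE, 600.0, seed=101)
    return rec, truth


@pytest.fixture(scope="session")
def sleep_recording():
    rec, truth = syn.generate_recording(syn.SLEEP_PROFILE, 600.0, seed=102)
    return rec, truth


@pytest.fixture(scope="session")
def obbb_recording():
    rec, truth = syn.generate_recording(syn.OBBB_PROFILE, 600.0, seed=103)
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
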