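import warnings

import numpy as np
import pytest

from orsound import synth


def pytest_configure(config):
    warnings.filterwarnings(
        "ignore", message=".*FastICA did not converge.*")
    warnings.filterwarnings(
        "ignore", message=".*Montage name.*deprecated.*")


@pytest.fixture(scope="session")
def small_cfg():
    """Short two-block study used by most unit tests."""
    return synth.SynthConfig(
        n_participants=1, n_blocks=2, blocks_per_condition=1,
        block_duration_s=30.0, audio_fs=8000.0, eeg_fs=125.0,
        feature_rate=125.0, seed=11,
    )


@pytest.fixture(scope="session")
def truth(small_cfg):
    gt = synth.default_ground_truth(small_cfg)
    gt.time_slope = 0.0
    return gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
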