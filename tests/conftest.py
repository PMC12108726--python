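import logging

import numpy as np
import pytest

from avsmotion import MotionDirectionAVS, enumerate_ideal_dataset

logging.getLogger("avsmotion").setLevel(logging.ERROR)
logging.getLogger("avsmotion.mixture").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ideal_32():
    """Full ideal index-vector dataset of the 32x32 retina (8192 vectors)."""
    return enumerate_ideal_dataset(32, 32)


@pytest.fixture(scope="session")
def trained_avs():
    """AVS trained on the full ideal dataset; shared across tests."""
    return MotionDirectionAVS(random_state=0, calibration_retries=3).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
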