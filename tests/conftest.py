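import numpy as np
import pytest

from eggkit import SyntheticSpec, gen_egg
from eggkit.preprocess import antialias_downsample


@pytest.fixture(scope="session")
def clean_3cpm_rec4():
    """Noise-free 3 cpm 4-channel recording, 30 min, downsampled to 4 Hz."""
    spec = SyntheticSpec(freq_cpm=3.0, snr_db=None, duration_min=30.0, seed=7)
    return antialias_downsample(gen_egg(spec))


@pytest.fixture(scope="session")
def noisy_3cpm_rec():
    """3 cpm at SNR 10 dB, 30 min, raw 200 Hz (with a meal in the header)."""
    spec = SyntheticSpec(
        freq_cpm=3.0, snr_db=10.0, duration_min=30.0, seed=11,
        meal_start_s=600.0, meal_end_s=720.0,
    )
    return gen_egg(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
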