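import numpy as np
import pytest
from hypothesis import settings

from temposeg.synthetic import Disk, SyntheticSpec, Waveform, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_movie():
    """Small, clean synthetic movie: 24x24, 256 frames, disk radius 7.

    Short cycle (64 frames) with continuous repolarization so every window
    of >= 16 frames carries signal; high SNR so segmentations are exact.
    """
    spec = SyntheticSpec(
        height=24,
        width=24,
        n_frames=256,
        shape=Disk(center=(11.5, 11.5), radius=7.0),
        waveform=Waveform(period_frames=64, upstroke_frames=3, apd_frames=64),
        noise_sigma_object=0.01,
        noise_sigma_background=0.01,
        seed=7,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
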