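import numpy as np
import pytest

from ussync import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_texture(shape=(128, 128), grain=2.0, seed=0):
    """Speckle-like trackable texture for tracking tests."""
    return sg._base_texture(shape, grain, np.random.default_rng(seed))


def spectral_shift(img, dx, dy):
    """Exact (periodic) sub-pixel shift of image content by (dx, dy) pixels."""
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    shifted = np.fft.ifft2(
        np.fft.fft2(img) * np.exp(-2j * np.pi * (kx * dx + ky * dy))
    )
    return np.real(shifted)


@pytest.fixture(scope="session")
def small_trial():
    """A short ground-truthed trial: 8 s, two twitches, default imaging."""
    timing = sg.TimingModel()
    schedule = sg.TwitchSchedule(onsets=np.array([2.0, 5.0]),
                                 region_centre=(64.0, 64.0))
    meta, ifis = sg.generate_true_frame_times(timing, 8.0, seed=3)
    images, truth = sg.generate_speckle_sequence(meta, schedule, seed=3)
    return {
        "timing": timing,
        "schedule": schedule,
        "times": meta,
        "ifis": ifis,
        "images": images,
        "truth": truth,
    }
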