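import numpy as np
import pytest

from ssaeeg import EEGRecording, EpochingConfig, SyntheticConfig
from ssaeeg.synthetic_eeg import DEFAULT_PHASES

FS = 128.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def epoch_cfg():
    return EpochingConfig()


@pytest.fixture
def tone_epoch():
    """One 3-s epoch of a unit 10-Hz cosine at 128 Hz (384 samples)."""
    t = np.arange(384) / FS
    return np.cos(2 * np.pi * 10.0 * t)


@pytest.fixture
def short_synthetic_config():
    """Scaled-down generator config for fast structural tests (2-min recording)."""
    import dataclasses

    return dataclasses.replace(
        SyntheticConfig(), duration_s=120.0, n_recordings=3, fade_s=5.0
    )


def make_recording(samples, fs=FS, **kw):
    return EEGRecording(samples=np.asarray(samples, dtype=float), fs=fs, **kw)


@pytest.fixture
def zeros_recording():
    """A 30-s all-zero recording (valid but spectrally degenerate)."""
    return make_recording(np.zeros(int(30 * FS)))


@pytest.fixture
def maintenance_recording(rng):
    """30 s of maintenance-like EEG: delta + dense 11-Hz spindles + noise."""
    n = int(30 * FS)
    t = np.arange(n) / FS
    delta = 20.0 * np.sin(2 * np.pi * 1.2 * t)
    spindle_env = 0.5 * (1 + np.sign(np.sin(2 * np.pi * 0.25 * t)))  # 2 s on / 2 s off
    alpha = 15.0 * spindle_env * np.sin(2 * np.pi * 11.0 * t)
    noise = 2.0 * rng.standard_normal(n)
    return make_recording(delta + alpha + noise)
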