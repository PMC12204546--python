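import numpy as np
import pytest

from ppgq.io_formats import Condition, PPGRecording
from ppgq.synthetic import WaveformConfig, generate_recording


@pytest.fixture
def clean_recording():
    """A clean generated recording (no noise, wander, or jitter).

    75 bpm puts one beat on exactly 80 samples at 100 Hz, so every pulse is
    sample-aligned and bit-identical.
    """
    cfg = WaveformConfig(mean_hr=75.0, noise_sd=0.0, wander_amp=0.0, hr_sd=0.0, seed=42)
    rec, gt = generate_recording(cfg)
    return rec, gt, cfg


@pytest.fixture
def noisy_recording():
    """A default-quality generated recording."""
    cfg = WaveformConfig(seed=7)
    rec, gt = generate_recording(cfg)
    return rec, gt, cfg


@pytest.fixture
def sine_recording():
    """100 + sin(2*pi*1.2 t), 30 s at 100 Hz."""
    fs = 100.0
    t = np.arange(3000) / fs
    x = 100.0 + np.sin(2 * np.pi * 1.2 * t)
    return PPGRecording("sine", Condition.SUPINE, fs, x)
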