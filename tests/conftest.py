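import numpy as np
import pytest

from semg_motionmap.signal_processing import EmgRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sine_recording():
    """1 s of pure 50 Hz and 80 Hz unit sines at 1 kHz on two channels."""
    fs = 1000.0
    t = np.arange(int(2 * fs)) / fs
    return EmgRecording(
        samples=np.vstack([np.sin(2 * np.pi * 50 * t), np.sin(2 * np.pi * 80 * t)]),
        fs=fs,
        channel_names=["tone50", "tone80"],
    )
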