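import sys
import pathlib

import numpy as np
import pytest

from bbnet.recording import EEGRecording, MONTAGE_14

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for tests.oracles


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def make_recording():
    """Factory for simple multichannel recordings from per-channel signals."""

    def _make(signals, fs=128.0, labels=None, **annotations):
        data = np.atleast_2d(np.asarray(signals, dtype=float))
        if labels is None:
            labels = MONTAGE_14[: data.shape[0]]
        return EEGRecording(data, fs=fs, channel_labels=labels, **annotations)

    return _make


@pytest.fixture
def sine_recording(make_recording):
    """One channel: unit-amplitude 6 Hz sinusoid, 60 s at 128 Hz."""
    t = np.arange(60 * 128) / 128.0
    return make_recording([np.sin(2 * np.pi * 6.0 * t)])
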