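"""Core EEG recording container and study-wide conventions.

The package analyzes 14-channel scalp EEG recorded with a wireless headset on
the international 10-20 montage at 128 Hz, in three experimental states
(before, during and after binaural-beat stimulation) across three stimulation
groups (alpha-, beta- and gamma-band beats).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Default 14-channel 10-20 montage, in acquisition order.
MONTAGE_14 = (
    "AF3", "F7", "F3", "FC5", "FC6", "F4", "F8", "AF4",
    "T3", "T4", "P7", "O1", "O2", "P8",
)

#: Experimental states: before, during and after binaural-beat stimulation.
STATES = ("Pre-BB", "Du-BB", "Post-BB")

#: Stimulation groups: A = 10 Hz (alpha), B = 14 Hz (beta), C = 30 Hz (gamma) beats.
GROUPS = ("A", "B", "C")


@dataclass
class EEGRecording:
    """Multichannel EEG time series with study annotations.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : tuple of str
        Ordered, unique channel names (10-20 convention).
    state, group, subject_id : str, optional
        Study annotations (``Pre-BB``/``Du-BB``/``Post-BB``, ``A``/``B``/``C``).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = MONTAGE_14
    state: str | None = None
    group: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.state is not None and self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``data`` replaced, annotations kept."""
        return replace(self, data=np.asarray(data, dtype=float))

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by (case-insensitive) label."""
        labels = [c.lower() for c in self.channel_labels]
        try:
            idx = labels.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None
        return self.data[idx]
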