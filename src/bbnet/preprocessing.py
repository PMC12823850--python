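"""EEG cleaning: detrending, Butterworth band-pass filtering, artifact rejection.

The cleaning chain removes DC offset and linear drift, band-passes 1-45 Hz
with a 5th-order Butterworth IIR design, and drops fixed-length epochs whose
peak absolute amplitude exceeds a threshold on any channel (a deterministic
stand-in for visual artifact inspection). A warning is emitted when more than
10% of epochs are rejected, the bound used for acceptable recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

#: Rejecting more than this fraction of epochs is flagged as suspect data.
MAX_REJECTION_FRACTION = 0.10


class HighRejectionWarning(UserWarning):
    """Raised as a warning when the artifact rejection rate exceeds 10%."""


@dataclass
class RejectionReport:
    """Bookkeeping for amplitude-threshold artifact rejection."""

    n_epochs_total: int
    n_epochs_rejected: int
    rejected_indices: list
    criterion: str

    @property
    def rejection_fraction(self) -> float:
        return self.n_epochs_rejected / self.n_epochs_total


def detrend(rec: EEGRecording) -> EEGRecording:
    """Remove per-channel mean and best-fit linear trend."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to detrend")
    return rec.with_data(signal.detrend(rec.data, axis=1, type="linear"))


def design_bandpass(low=1.0, high=45.0, order=5, fs=128.0):
    """Butterworth band-pass second-order sections for the given edges."""
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < "
                         f"Nyquist ({nyq} Hz)")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: EEGRecording, low=1.0, high=45.0, order=5,
                    causal=False) -> EEGRecording:
    """Band-pass filter each channel.

    By default the filter is applied forward and backward (zero phase,
    effective order doubled) so that cross-channel phase relations — and
    hence coherence — are untouched. ``causal=True`` applies a single
    forward pass instead, reproducing a conventional real-time ``filter``
    call at the cost of frequency-dependent phase lag.
    """
    sos = design_bandpass(low, high, order, rec.fs)
    if causal:
        out = signal.sosfilt(sos, rec.data, axis=1)
    else:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(out)


def reject_artifacts(rec: EEGRecording, epoch_len=2.0, amp_thresh=100.0):
    """Drop non-overlapping epochs whose peak |amplitude| exceeds ``amp_thresh``.

    The recording is cut into consecutive ``epoch_len``-second epochs (a
    trailing partial epoch is kept as its own epoch); an epoch is rejected
    when *any* channel exceeds ``amp_thresh`` microvolts in absolute value.
    Surviving epochs are concatenated in order.

    Returns ``(cleaned_recording, RejectionReport)``; raises if every epoch
    is rejected. Emits :class:`HighRejectionWarning` above a 10% rate.
    """
    samples_per_epoch = int(round(epoch_len * rec.fs))
    if samples_per_epoch < 1:
        raise ValueError("epoch_len must cover at least one sample")
    n_epochs = int(np.ceil(rec.n_samples / samples_per_epoch))
    keep, rejected = [], []
    for e in range(n_epochs):
        sl = slice(e * samples_per_epoch, min((e + 1) * samples_per_epoch,
                                              rec.n_samples))
        epoch = rec.data[:, sl]
        if np.abs(epoch).max() > amp_thresh:
            rejected.append(e)
        else:
            keep.append(epoch)
    if not keep:
        raise ValueError("all epochs exceeded the artifact threshold; "
                         "nothing left to analyze")
    report = RejectionReport(
        n_epochs_total=n_epochs, n_epochs_rejected=len(rejected),
        rejected_indices=rejected,
        criterion=f"peak |amplitude| > {amp_thresh} uV in any channel, "
                  f"{epoch_len} s epochs")
    if report.rejection_fraction > MAX_REJECTION_FRACTION:
        warnings.warn(
            f"artifact rejection rate {report.rejection_fraction:.1%} exceeds "
            f"the {MAX_REJECTION_FRACTION:.0%} acceptability bound",
            HighRejectionWarning, stacklevel=2)
    return rec.with_data(np.concatenate(keep, axis=1)), report


def preprocess(rec: EEGRecording, low=1.0, high=45.0, order=5, causal=False,
               epoch_len=2.0, amp_thresh=100.0):
    """Full cleaning chain: detrend -> band-pass -> artifact rejection."""
    out = detrend(rec)
    out = bandpass_filter(out, low=low, high=high, order=order, causal=causal)
    return reject_artifacts(out, epoch_len=epoch_len, amp_thresh=amp_thresh)
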