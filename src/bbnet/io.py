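"""Reading and writing EEG recordings and tabular study outputs.

EEG input is accepted as EDF (via :mod:`mne`) or as headered CSV whose first
column is time in seconds and remaining columns are channels in microvolts.
All tabular outputs (band power, coherence, node metrics, digit-span
sessions) are tab-separated text.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .recording import EEGRecording


def write_csv(rec: EEGRecording, path) -> None:
    """Write a recording as headered CSV: ``time`` column plus one per channel."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for label, row in zip(rec.channel_labels, rec.data):
        # 1e-5 uV quantization keeps files compact; time stays exact
        df[label] = np.round(row, 5)
    df.to_csv(path, index=False)


def read_csv(path, state=None, group=None, subject_id=None) -> EEGRecording:
    """Read a headered CSV recording (first column time in seconds)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    labels = tuple(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    return EEGRecording(data, fs=round(fs, 6), channel_labels=labels,
                        state=state, group=group, subject_id=subject_id)


def read_edf(path, state=None, group=None, subject_id=None) -> EEGRecording:
    """Read an EDF recording; channel amplitudes are converted to microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(data, fs=float(raw.info["sfreq"]),
                        channel_labels=tuple(raw.ch_names),
                        state=state, group=group, subject_id=subject_id)


def read_recording(path, **annotations) -> EEGRecording:
    """Dispatch on file suffix: ``.edf`` via mne, anything else as CSV."""
    path = pathlib.Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, **annotations)
    return read_csv(path, **annotations)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a long-format result table as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
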