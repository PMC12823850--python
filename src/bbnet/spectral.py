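"""Welch spectral estimation, relative band power and pairwise coherence.

Power spectral densities use Welch's method with a 4-s Hann window, 2-s
overlap and a 512-point FFT, which at 128 Hz gives a 0.25 Hz bin spacing.
Relative band power normalizes the power in each of the four EEG bands
(theta 4-8, alpha 8-12, beta 13-29, gamma 30-45 Hz) by the total power from
1 to 45 Hz. Functional connectivity is the magnitude-squared coherence

    C_ab(f) = |P_ab(f)|^2 / (P_aa(f) * P_bb(f))          in [0, 1],

averaged over the frequency bins of a band to give one channel-by-channel
coherence matrix per band and recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .recording import EEGRecording


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, closed interval [lo, hi] Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo < self.hi:
            raise ValueError("band must satisfy 0 <= lo < hi")


#: The four analysis bands. Theta and alpha share the printed 8 Hz edge; the
#: 8 Hz bin is assigned to theta only (the lower band wins shared edges).
DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 29.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BANDS = {b.name: b for b in DEFAULT_BANDS}

#: Normalization range for relative band power (Hz).
TOTAL_POWER_RANGE = (1.0, 45.0)


@dataclass
class SpectralEstimate:
    """Welch PSD for all channels of one recording."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs), power per Hz
    channel_labels: tuple
    params: dict

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class CoherenceMatrix:
    """Band-averaged magnitude-squared coherence between all channel pairs."""

    values: np.ndarray  # (n_chan, n_chan), symmetric, unit diagonal
    band: BandDefinition
    channel_labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("coherence matrix must be symmetric")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("coherence values must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)


def band_mask(freqs, band: BandDefinition, band_set=DEFAULT_BANDS) -> np.ndarray:
    """Boolean mask of bins belonging to ``band``.

    Intervals are closed ``[lo, hi]``; when two bands of ``band_set`` share
    an edge frequency (theta/alpha at 8 Hz), the shared bin goes to the lower
    band only, so band assignment is a partition.
    """
    freqs = np.asarray(freqs)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    for other in band_set:
        if other.name != band.name and np.isclose(other.hi, band.lo):
            mask &= freqs > band.lo
    return mask


def _welch_params(fs, window_len, overlap, nfft):
    nperseg = int(round(window_len * fs))
    noverlap = int(round(overlap * fs))
    if not 0 <= noverlap < nperseg:
        raise ValueError("overlap must be shorter than the window")
    if nfft < nperseg:
        raise ValueError("nfft must be at least the window length in samples")
    return nperseg, noverlap


def welch_psd(rec: EEGRecording, window_len=4.0, overlap=2.0, nfft=512,
              window="hann") -> SpectralEstimate:
    """Welch PSD of every channel (density scaling, one-sided).

    Defaults follow the study configuration: 4-s Hann segments, 2-s overlap,
    512-point FFT -> 0.25 Hz bins at 128 Hz.
    """
    nperseg, noverlap = _welch_params(rec.fs, window_len, overlap, nfft)
    if rec.n_samples < nperseg:
        raise ValueError(f"recording ({rec.duration:.1f} s) is shorter than "
                         f"one {window_len} s Welch window")
    freqs, psd = signal.welch(rec.data, fs=rec.fs, window=window,
                              nperseg=nperseg, noverlap=noverlap, nfft=nfft,
                              axis=1, scaling="density")
    return SpectralEstimate(freqs, psd, rec.channel_labels,
                            dict(window_len_s=window_len, overlap_s=overlap,
                                 nfft=nfft, window_type=window))


def band_power(spec: SpectralEstimate, lo, hi, mask=None) -> np.ndarray:
    """Integrated power per channel over a closed frequency interval."""
    if mask is None:
        mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bin falls inside [{lo}, {hi}] Hz")
    df = spec.bin_spacing
    return spec.psd[:, mask].sum(axis=1) * df


def relative_band_power(spec: SpectralEstimate, band: BandDefinition,
                        total_range=TOTAL_POWER_RANGE,
                        band_set=DEFAULT_BANDS) -> np.ndarray:
    """Per-channel fraction of 1-45 Hz power lying in ``band`` (in [0, 1])."""
    lo, hi = total_range
    if not (lo <= band.lo and band.hi <= hi):
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] must lie "
                         f"inside the normalization range {total_range}")
    num = band_power(spec, band.lo, band.hi,
                     mask=band_mask(spec.freqs, band, band_set))
    den = band_power(spec, lo, hi)
    return num / den


def _segment_ffts(data, fs, window_len, overlap, nfft, window):
    """Hann-tapered, mean-detrended segment FFTs, shape (n_chan, n_seg, n_bin)."""
    nperseg, noverlap = _welch_params(fs, window_len, overlap, nfft)
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < nperseg:
        raise ValueError("input shorter than one Welch window")
    step = nperseg - noverlap
    n_seg = (data.shape[-1] - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = data[..., idx]                      # (n_chan, n_seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    taper = signal.get_window(window, nperseg)
    return np.fft.rfft(segs * taper, n=nfft, axis=-1), n_seg


def msc_spectrum(x, y, fs, window_len=4.0, overlap=2.0, nfft=512,
                 window="hann"):
    """Magnitude-squared coherence between two channels vs frequency.

    Uses the same segmentation and taper as :func:`welch_psd`. At least two
    Welch segments are required: the single-segment estimator is identically
    1 at every frequency and carries no information.
    """
    X, n_seg = _segment_ffts(np.vstack([x, y]), fs, window_len, overlap,
                             nfft, window)
    if n_seg < 2:
        raise ValueError("magnitude-squared coherence needs >= 2 Welch "
                         "segments (a single segment gives identically 1)")
    sxx = (np.abs(X[0]) ** 2).mean(axis=0)
    syy = (np.abs(X[1]) ** 2).mean(axis=0)
    sxy = (X[0] * np.conj(X[1])).mean(axis=0)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    return freqs, np.clip(np.nan_to_num(coh), 0.0, 1.0)


def coherence_cube(rec: EEGRecording, window_len=4.0, overlap=2.0, nfft=512,
                   window="hann"):
    """All-pairs magnitude-squared coherence, shape (n_chan, n_chan, n_bin).

    Computes each channel's segment FFTs once and forms all cross-spectra by
    outer products, which is what makes whole-study coherence analysis cheap.
    """
    X, n_seg = _segment_ffts(rec.data, rec.fs, window_len, overlap, nfft,
                             window)
    if n_seg < 2:
        raise ValueError("magnitude-squared coherence needs >= 2 Welch "
                         "segments")
    cross = np.einsum("asf,bsf->abf", X, np.conj(X)) / n_seg
    auto = np.real(np.einsum("aaf->af", cross))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(cross) ** 2 / (auto[:, None, :] * auto[None, :, :])
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.fs)
    return freqs, coh


def band_coherence_matrix(rec: EEGRecording, band: BandDefinition,
                          window_len=4.0, overlap=2.0, nfft=512,
                          window="hann", band_set=DEFAULT_BANDS) -> CoherenceMatrix:
    """Channel-by-channel coherence averaged over the bins of one band."""
    freqs, coh = coherence_cube(rec, window_len, overlap, nfft, window)
    mask = band_mask(freqs, band, band_set)
    if not mask.any():
        raise ValueError(f"no frequency bin falls inside band {band.name}")
    values = coh[:, :, mask].mean(axis=2)
    values = 0.5 * (values + values.T)  # kill numerical asymmetry
    np.fill_diagonal(values, 1.0)
    return CoherenceMatrix(values, band, rec.channel_labels)


def all_band_coherence(rec: EEGRecording, bands=DEFAULT_BANDS, **welch_kw):
    """One :class:`CoherenceMatrix` per band, sharing a single FFT pass."""
    freqs, coh = coherence_cube(rec, **{"window_len": 4.0, "overlap": 2.0,
                                        "nfft": 512, "window": "hann",
                                        **welch_kw})
    out = {}
    for band in bands:
        mask = band_mask(freqs, band, bands)
        values = coh[:, :, mask].mean(axis=2)
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
        out[band.name] = CoherenceMatrix(values, band, rec.channel_labels)
    return out


def coherence_long_frame(matrices, subject=None, state=None) -> pd.DataFrame:
    """Long-format table (subject, state, band, chan_a, chan_b, value)."""
    rows = []
    for band_name, cm in matrices.items():
        labels = cm.channel_labels
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                rows.append({"subject": subject, "state": state,
                             "band": band_name, "chan_a": labels[a],
                             "chan_b": labels[b],
                             "value": cm.values[a, b]})
    return pd.DataFrame(rows)
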