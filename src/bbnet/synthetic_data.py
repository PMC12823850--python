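"""Synthetic EEG, binaural-beat stimuli and digit-span sessions with known truth.

Every downstream stage of the pipeline (spectral estimation, coherence graphs,
statistics) is exercised on data from this module, whose spectral and network
structure is known in closed form:

* Band-limited oscillatory sources are synthesized in the frequency domain
  with an exactly flat power spectrum inside their band, so auto- and
  cross-spectral densities are analytic.
* Channel pairs driven by a shared source with per-channel signal-to-noise
  ratios ``snr_a`` and ``snr_b`` (signal-to-noise measured per frequency bin
  against noise of the *same* spectral shape) have magnitude-squared coherence

      MSC = (snr_a * snr_b) / ((1 + snr_a) * (1 + snr_b))

  at the source frequency, which the Welch estimator must recover.
* Study recordings mix per-band shared and channel-private oscillations over a
  pink-noise background; in the high-SNR limit the band coherence between two
  channels approaches the squared shared-variance fraction of the band source.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .behavior_scoring import (
    FIRST_SEQUENCE_LENGTH,
    DigitSpanSession,
    Round,
    advances,
)
from .recording import GROUPS, MONTAGE_14, STATES, EEGRecording

#: Canonical band ranges (Hz) used to map a named effect onto model sources.
BAND_RANGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 29.0),
    "gamma": (30.0, 45.0),
}


# ---------------------------------------------------------------------------
# low-level noise synthesis
# ---------------------------------------------------------------------------

def _band_limited_noise(rng, shape, n_samples, fs, lo, hi):
    """Gaussian noise with unit variance and an exactly flat spectrum in [lo, hi].

    Synthesized in the frequency domain (independent complex-Gaussian Fourier
    coefficients on the in-band bins, zero elsewhere), so two independent
    draws have identical expected power spectral density — the property the
    coherence oracle relies on. Returns an array of ``shape + (n_samples,)``.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    mask[0] = False
    if n_samples % 2 == 0:
        mask[-1] = False
    m = int(mask.sum())
    if m == 0:
        raise ValueError(f"band [{lo}, {hi}] Hz contains no frequency bin "
                         f"at {n_samples} samples, fs={fs}")
    shape = tuple(np.atleast_1d(shape))
    coeff = rng.standard_normal(shape + (m, 2))
    spectrum = np.zeros(shape + (freqs.size,), dtype=complex)
    spectrum[..., mask] = coeff[..., 0] + 1j * coeff[..., 1]
    x = np.fft.irfft(spectrum, n_samples)
    # E[var] of the raw irfft is 4 m / n^2; rescale to unit variance.
    x *= n_samples / (2.0 * np.sqrt(m))
    return x


def _pink_noise(rng, shape, n_samples, fs, sd, exponent=1.0):
    """1/f^exponent background noise with expected per-channel SD ``sd``."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    if n_samples % 2 == 0:
        amp[-1] = 0.0
    shape = tuple(np.atleast_1d(shape))
    coeff = rng.standard_normal(shape + (freqs.size, 2))
    spectrum = (coeff[..., 0] + 1j * coeff[..., 1]) * amp
    x = np.fft.irfft(spectrum, n_samples)
    expected_var = 4.0 * np.sum(amp**2) / n_samples**2
    x *= sd / np.sqrt(expected_var)
    return x


# ---------------------------------------------------------------------------
# coherent channel-pair generator (coherence oracle)
# ---------------------------------------------------------------------------

def theoretical_pair_msc(snr_a: float, snr_b: float) -> float:
    """Closed-form magnitude-squared coherence of a common-source pair."""
    return (snr_a * snr_b) / ((1.0 + snr_a) * (1.0 + snr_b))


def generate_common_source_pair(f0, snr_a, snr_b, fs=128.0, duration=300.0,
                                seed=0, bandwidth=2.0) -> EEGRecording:
    """Two channels sharing a narrowband source at ``f0`` with known coherence.

    Channel ``i`` is ``sqrt(snr_i) * s + m_i + w_i`` where ``s`` is a
    unit-variance narrowband source at ``f0`` (flat over ``bandwidth`` Hz),
    ``m_i`` is an independent narrowband noise with the *same* spectrum as
    ``s`` — so that the per-bin signal-to-noise ratio at ``f0`` equals
    ``snr_i`` exactly — and ``w_i`` is unit-variance white noise providing a
    broadband floor (its density at ``f0`` is <1% of the narrowband density,
    so it perturbs the coherence oracle negligibly).

    The true magnitude-squared coherence across the source band is
    ``theoretical_pair_msc(snr_a, snr_b)``.
    """
    if snr_a <= 0 or snr_b <= 0:
        raise ValueError("snr values must be positive")
    if not 0 < f0 - bandwidth / 2 or not f0 + bandwidth / 2 < fs / 2:
        raise ValueError(f"source band around f0={f0} Hz must lie strictly "
                         f"inside (0, {fs / 2}) Hz")
    if duration < 32:
        raise ValueError("duration must be >= 32 s for a stable Welch estimate")
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17]))
    lo, hi = f0 - bandwidth / 2, f0 + bandwidth / 2
    s = _band_limited_noise(rng, (), n, fs, lo, hi)
    m = _band_limited_noise(rng, (2,), n, fs, lo, hi)
    w = rng.standard_normal((2, n))
    gains = np.sqrt([snr_a, snr_b])
    data = gains[:, None] * s[None, :] + m + w
    return EEGRecording(data, fs=fs, channel_labels=("CH1", "CH2"))


def estimate_pair_msc(rec: EEGRecording, f0, bandwidth=2.0, **welch_kw) -> float:
    """Welch-estimated coherence of a common-source pair at its source band.

    Averages the magnitude-squared coherence over the frequency bins in the
    interior of the source band (edge bins are excluded because the Welch
    window smears part of their energy outside the band).
    """
    from .spectral import msc_spectrum

    freqs, coh = msc_spectrum(rec.data[0], rec.data[1], rec.fs, **welch_kw)
    df = freqs[1] - freqs[0]
    sel = np.abs(freqs - f0) <= max(bandwidth / 2.0 - df, df / 2.0)
    return float(coh[sel].mean())


# ---------------------------------------------------------------------------
# study recordings: 14-channel EEG with per-band shared sources
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharedSource:
    """One band-limited oscillatory source mixed into all channels.

    ``amplitude`` is the per-unit-weight RMS contribution in microvolts;
    ``weights`` scales it per channel (regional amplitude profile);
    ``shared_fraction`` is the fraction rho of the source variance that is
    common across channels (the rest is channel-private noise of identical
    spectrum), so in the high-SNR limit the band coherence between two
    channels approaches rho**2.
    """

    band: tuple
    amplitude: float
    weights: tuple
    shared_fraction: float = 0.6

    def __post_init__(self):
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < lo < hi")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SourceMixModel:
    """Generative model for one subject's multichannel EEG."""

    sources: tuple
    n_channels: int = 14
    fs: float = 128.0
    duration: float = 300.0
    noise_sd: float = 8.0
    pink_exponent: float = 1.0
    seed: int = 0
    channel_labels: tuple = MONTAGE_14

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (the coherence oracle "
                             "is undefined at zero background noise)")
        for src in self.sources:
            if self.fs <= 2 * src.band[1]:
                raise ValueError(f"fs={self.fs} must exceed twice the highest "
                                 f"source frequency {src.band[1]}")
            if len(src.weights) != self.n_channels:
                raise ValueError("source weight vectors must have one entry "
                                 "per channel")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")


@dataclass(frozen=True)
class EffectSpec:
    """Group-by-state effect planted on one frequency band.

    For the during- and post-stimulation states, sources overlapping ``band``
    have their amplitude multiplied by ``power_delta`` and their shared
    fraction shifted by ``coherence_delta`` relative to the pre-stimulation
    state.
    """

    band: str
    power_delta: float = 1.0
    coherence_delta: float = 0.0
    states: tuple = STATES

    def __post_init__(self):
        if self.band not in BAND_RANGES:
            raise ValueError(f"unknown band {self.band!r}; expected one of "
                             f"{sorted(BAND_RANGES)}")
        if self.power_delta <= 0:
            raise ValueError("power_delta must be positive")
        if tuple(self.states) != STATES:
            raise ValueError(f"states must be exactly {STATES}")


def _bands_overlap(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def generate_study_recording(model: SourceMixModel, effect: EffectSpec | None,
                             state: str, subject_id=None, group=None) -> EEGRecording:
    """One 14-channel recording for a given subject model and state.

    Deterministic given ``(model, effect, state)``; the random stream is keyed
    on ``(model.seed, state)`` so the same subject produces *different*
    realizations per state but identical output on repeated calls.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    n = int(round(model.duration * model.fs))
    state_idx = STATES.index(state)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(model.seed) & 0x7FFFFFFF, 101 + state_idx]))
    effect_range = BAND_RANGES[effect.band] if effect is not None else None
    data = _pink_noise(rng, (model.n_channels,), n, model.fs,
                       model.noise_sd, model.pink_exponent)
    for src in model.sources:
        amp = src.amplitude
        rho = src.shared_fraction
        if (effect is not None and state != "Pre-BB"
                and _bands_overlap(src.band, effect_range)):
            amp *= effect.power_delta
            rho = float(np.clip(rho + effect.coherence_delta, 0.0, 1.0))
        lo, hi = src.band
        shared = _band_limited_noise(rng, (), n, model.fs, lo, hi)
        private = _band_limited_noise(rng, (model.n_channels,), n, model.fs, lo, hi)
        mix = np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * private
        data += amp * np.asarray(src.weights, dtype=float)[:, None] * mix
    return EEGRecording(data, fs=model.fs, channel_labels=model.channel_labels,
                        state=state, group=group, subject_id=subject_id)


# regional amplitude profiles: a fixed anterior-posterior gradient per band so
# pairwise coherences are heterogeneous rather than all sitting at one value
_CHANNEL_POS = np.linspace(0.0, 1.0, 14)
_BASE_WEIGHTS = {
    "theta": 1.0 + 0.25 * np.cos(np.pi * _CHANNEL_POS),          # frontal-dominant
    "alpha": 1.0 + 0.25 * np.cos(np.pi * (1 - _CHANNEL_POS)),    # posterior-dominant
    "beta": 1.0 + 0.15 * np.sin(2 * np.pi * _CHANNEL_POS),
    "gamma": np.full(14, 1.0),
}

#: Default per-band source RMS amplitude (microvolts per unit weight) and
#: shared-variance fraction for the simulated resting study.
DEFAULT_BAND_AMPLITUDES = {"theta": 7.0, "alpha": 8.0, "beta": 6.0, "gamma": 4.0}
DEFAULT_SHARED_FRACTIONS = {"theta": 0.55, "alpha": 0.55, "beta": 0.55, "gamma": 0.50}


def default_study_model(seed, *, duration=300.0, fs=128.0, noise_sd=8.0,
                        amplitudes=None, shared_fractions=None,
                        subject_jitter=True) -> SourceMixModel:
    """Per-subject source-mix model with one band-limited source per EEG band.

    With ``subject_jitter`` the band amplitudes, channel weights and shared
    fractions receive multiplicative/additive subject-level perturbations
    (keyed on ``seed``) so that between-subject variance is non-degenerate.
    """
    amplitudes = dict(DEFAULT_BAND_AMPLITUDES, **(amplitudes or {}))
    shared_fractions = dict(DEFAULT_SHARED_FRACTIONS, **(shared_fractions or {}))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7]))
    sources = []
    for band, (lo, hi) in BAND_RANGES.items():
        amp = amplitudes[band]
        rho = shared_fractions[band]
        weights = np.array(_BASE_WEIGHTS[band], dtype=float)
        if subject_jitter:
            amp *= float(np.exp(rng.normal(0.0, 0.10)))
            rho = float(np.clip(rho + rng.normal(0.0, 0.04), 0.05, 0.95))
            weights = weights * (1.0 + rng.normal(0.0, 0.08, size=weights.size))
        sources.append(SharedSource((lo, hi), amp, tuple(weights), rho))
    return SourceMixModel(tuple(sources), fs=fs, duration=duration,
                          noise_sd=noise_sd, seed=int(seed) & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# binaural-beat stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """A dichotic pure-tone pair: one carrier per ear."""

    f_left: float = 400.0
    f_right: float = 410.0
    fs_audio: float = 8000.0
    duration: float = 2.0

    def __post_init__(self):
        if self.fs_audio <= 2 * max(self.f_left, self.f_right):
            raise ValueError("fs_audio must exceed twice the highest carrier "
                             "frequency (aliasing)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def beat_frequency(self) -> float:
        return abs(self.f_right - self.f_left)


def generate_bb_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Unit-amplitude stereo waveform, shape (2, n): row 0 left, row 1 right."""
    n = int(round(spec.duration * spec.fs_audio))
    t = np.arange(n) / spec.fs_audio
    return np.vstack([np.sin(2 * np.pi * spec.f_left * t),
                      np.sin(2 * np.pi * spec.f_right * t)])


def envelope_spectrum(x, fs) -> tuple:
    """Amplitude spectrum of the analytic (Hilbert) envelope of ``x``.

    Returns ``(freqs, magnitude)`` with the mean envelope level removed, so a
    dichotic tone pair summed at the listener shows its beat as a spectral
    peak at the carrier difference frequency.
    """
    env = np.abs(hilbert(np.asarray(x, dtype=float)))
    env = env - env.mean()
    mags = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(env.size, 1.0 / fs)
    return freqs, mags


def detect_beat_frequency(stereo, fs, rel_floor=1e-6) -> float:
    """Peak frequency of the summed channels' envelope spectrum (0 if flat)."""
    summed = np.asarray(stereo).sum(axis=0)
    freqs, mags = envelope_spectrum(summed, fs)
    if mags[1:].max() < rel_floor * summed.size:
        return 0.0
    return float(freqs[1:][np.argmax(mags[1:])])


# ---------------------------------------------------------------------------
# digit-span sessions
# ---------------------------------------------------------------------------

def generate_digit_span_session(p_correct_by_round, trials_per_round=5, seed=0,
                                round_time_mean_s=23.0, round_time_sd_s=3.0,
                                subject_id=None, state=None) -> DigitSpanSession:
    """Simulate one digit-span session with binomial recall per round.

    Round ``r`` draws ``Binomial(trials_per_round, p_correct_by_round[r])``
    correct recalls; the session stops after the first round scoring below
    the 60% advancement threshold. Per-round completion times are Gaussian
    (truncated at 5 s).
    """
    p = list(p_correct_by_round)
    if not 1 <= len(p) <= 5:
        raise ValueError("between 1 and 5 rounds are allowed")
    if any(not 0.0 <= pi <= 1.0 for pi in p):
        raise ValueError("round probabilities must lie in [0, 1]")
    if trials_per_round < 1:
        raise ValueError("need at least one trial per round")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 23]))
    rounds = []
    for i, pi in enumerate(p):
        n_correct = int(rng.binomial(trials_per_round, pi))
        time_s = float(max(5.0, rng.normal(round_time_mean_s, round_time_sd_s)))
        rnd = Round(FIRST_SEQUENCE_LENGTH + i, trials_per_round, n_correct, time_s)
        rounds.append(rnd)
        if not advances(rnd.score):
            break
    return DigitSpanSession(rounds, subject_id=subject_id, state=state)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the simulated three-group stimulation study.

    Defaults mirror the study design being emulated: 3 groups x 20 subjects
    x 3 states, 14 channels at 128 Hz, 5-minute recordings.
    """

    n_per_group: int = 20
    groups: tuple = GROUPS
    states: tuple = STATES
    duration: float = 300.0
    fs: float = 128.0
    noise_sd: float = 8.0
    effect: EffectSpec | None = None
    effect_group: str | None = "A"
    trials_per_round: int = 5
    #: round-wise recall probabilities before stimulation
    p_correct_base: tuple = (0.95, 0.92, 0.85, 0.72, 0.55)
    #: additive recall-probability boost after stimulation in the effect group
    behavior_boost: float = 0.08
    #: per-round completion-time reduction (s) after stimulation, effect group
    time_reduction_s: float = 2.0
    seed: int = 0

    def subject_ids(self):
        return [f"{g}{i + 1:02d}" for g in self.groups
                for i in range(self.n_per_group)]


def _subject_seed(cfg_seed, subject_index) -> int:
    ss = np.random.SeedSequence([int(cfg_seed) & 0x7FFFFFFF, 1009, subject_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def iter_study_recordings(cfg: StudyConfig):
    """Yield ``EEGRecording`` objects for every subject and state, lazily.

    The planted effect (``cfg.effect``) is applied only to subjects of
    ``cfg.effect_group``; every other group follows the null model.
    """
    idx = 0
    for group in cfg.groups:
        for i in range(cfg.n_per_group):
            subject_id = f"{group}{i + 1:02d}"
            model = default_study_model(_subject_seed(cfg.seed, idx),
                                        duration=cfg.duration, fs=cfg.fs,
                                        noise_sd=cfg.noise_sd)
            effect = cfg.effect if group == cfg.effect_group else None
            for state in cfg.states:
                yield generate_study_recording(model, effect, state,
                                               subject_id=subject_id, group=group)
            idx += 1


def simulate_behavior(cfg: StudyConfig):
    """Digit-span sessions for every subject and the Pre/Post states.

    Subject ability is a persistent random offset on the round recall
    probabilities; after stimulation the effect group gains
    ``cfg.behavior_boost`` recall probability and loses
    ``cfg.time_reduction_s`` per round.
    """
    sessions = []
    idx = 0
    for group in cfg.groups:
        for i in range(cfg.n_per_group):
            subject_id = f"{group}{i + 1:02d}"
            sseed = _subject_seed(cfg.seed, idx)
            rng = np.random.default_rng(np.random.SeedSequence([sseed, 31]))
            ability = rng.normal(0.0, 0.05)
            for state in ("Pre-BB", "Post-BB"):
                boost = (cfg.behavior_boost
                         if state == "Post-BB" and group == cfg.effect_group else 0.0)
                dt = (cfg.time_reduction_s
                      if state == "Post-BB" and group == cfg.effect_group else 0.0)
                p = np.clip(np.asarray(cfg.p_correct_base) + ability + boost, 0.0, 1.0)
                sessions.append(generate_digit_span_session(
                    p, trials_per_round=cfg.trials_per_round,
                    seed=int(np.random.SeedSequence(
                        [sseed, 37, ("Pre-BB", "Post-BB").index(state)]
                    ).generate_state(1)[0] & 0x7FFFFFFF),
                    round_time_mean_s=23.0 - dt,
                    subject_id=subject_id, state=state))
            idx += 1
    return sessions


def simulate_study_to_dir(cfg: StudyConfig, out_dir) -> dict:
    """Write a complete synthetic study (CSV EEG + digit-span TSV + manifest).

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    import json
    import pathlib

    from . import io as bio
    from .behavior_scoring import write_sessions_tsv

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = {}
    for rec in iter_study_recordings(cfg):
        fname = f"{rec.subject_id}_{rec.state.replace('-', '')}.csv"
        bio.write_csv(rec, out_dir / fname)
        entry = subjects.setdefault(
            rec.subject_id, {"id": rec.subject_id, "group": rec.group, "eeg": {}})
        entry["eeg"][rec.state] = fname
    behavior_path = out_dir / "digit_span.tsv"
    write_sessions_tsv(simulate_behavior(cfg), behavior_path)
    manifest = {
        "seed": cfg.seed,
        "config": {"fs": cfg.fs, "duration": cfg.duration, "states": list(cfg.states)},
        "digit_span": behavior_path.name,
        "subjects": list(subjects.values()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
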