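import numpy as np
import pytest

from bbnet import synthetic_data as sd
from bbnet.spectral import BANDS, band_coherence_matrix, msc_spectrum, welch_psd
from bbnet.spectral import relative_band_power
from bbnet.stats import paired_t


class TestCommonSourcePair:
    def test_identical_signal_limit_is_fully_coherent(self):
        rec = sd.generate_common_source_pair(6.0, 1e6, 1e6, duration=60,
                                             seed=0)
        assert sd.estimate_pair_msc(rec, 6.0) > 0.99

    def test_unit_snr_recovers_quarter_coherence(self):
        ests = [sd.estimate_pair_msc(
            sd.generate_common_source_pair(6.0, 1.0, 1.0, duration=300,
                                           seed=s), 6.0)
            for s in range(4)]
        assert np.mean(ests) == pytest.approx(0.25, abs=0.05)

    def test_vanishing_shared_signal_gives_no_coherence(self):
        ests = [sd.estimate_pair_msc(
            sd.generate_common_source_pair(6.0, 1e-4, 1e-4, duration=300,
                                           seed=s), 6.0)
            for s in range(4)]
        assert np.mean(ests) < 0.01 + 2.0 / 149  # estimator bias floor ~1/K

    def test_asymmetric_snr_closed_form(self):
        snr_a, snr_b = 4.0, 0.5
        theory = sd.theoretical_pair_msc(snr_a, snr_b)
        ests = [sd.estimate_pair_msc(
            sd.generate_common_source_pair(10.0, snr_a, snr_b, duration=300,
                                           seed=s), 10.0)
            for s in range(4)]
        assert np.mean(ests) == pytest.approx(theory, abs=0.05)

    def test_estimate_tightens_with_duration(self):
        # convergence of the Welch estimate toward the closed form
        errs = []
        for dur in (60.0, 600.0):
            ests = [sd.estimate_pair_msc(
                sd.generate_common_source_pair(8.0, 1.0, 1.0, duration=dur,
                                               seed=s), 8.0)
                for s in range(4)]
            errs.append(abs(np.mean(ests) - 0.25))
        assert errs[1] < max(errs[0], 0.02)

    def test_off_source_coherence_matches_estimator_bias(self):
        rec = sd.generate_common_source_pair(6.0, 1.0, 1.0, duration=300,
                                             seed=1)
        freqs, coh = msc_spectrum(rec.data[0], rec.data[1], rec.fs)
        far = (freqs > 20) & (freqs < 60)
        n_seg = 149
        se = (1.0 / n_seg) / np.sqrt(far.sum() / 8)
        assert coh[far].mean() == pytest.approx(1.0 / n_seg,
                                                abs=max(3 * se, 0.004))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_common_source_pair(70.0, 1.0, 1.0)  # above Nyquist
        with pytest.raises(ValueError):
            sd.generate_common_source_pair(6.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            sd.generate_common_source_pair(6.0, 1.0, 1.0, duration=10)


class TestStudyRecording:
    def test_same_seed_is_bit_identical(self):
        model = sd.default_study_model(5, duration=40)
        a = sd.generate_study_recording(model, None, "Pre-BB")
        b = sd.generate_study_recording(model, None, "Pre-BB")
        assert np.array_equal(a.data, b.data)

    def test_states_differ_in_realization(self):
        model = sd.default_study_model(5, duration=40)
        a = sd.generate_study_recording(model, None, "Pre-BB")
        b = sd.generate_study_recording(model, None, "Post-BB")
        assert not np.allclose(a.data, b.data)

    def test_unknown_state_rejected(self):
        model = sd.default_study_model(5, duration=40)
        with pytest.raises(ValueError):
            sd.generate_study_recording(model, None, "Mid-BB")

    def test_recording_shape_and_montage(self):
        model = sd.default_study_model(0, duration=40)
        rec = sd.generate_study_recording(model, None, "Du-BB")
        assert rec.n_channels == 14
        assert rec.channel_labels == sd.MONTAGE_14
        assert rec.n_samples == 40 * 128

    def test_power_delta_doubles_theta_band_power(self):
        eff = sd.EffectSpec("theta", power_delta=2.0)
        model = sd.default_study_model(3, duration=120, subject_jitter=False)
        pre = sd.generate_study_recording(model, eff, "Pre-BB")
        post = sd.generate_study_recording(model, eff, "Post-BB")
        ratios = []
        for rec in (pre, post):
            spec = welch_psd(rec)
            mask = (spec.freqs >= 4.5) & (spec.freqs <= 7.5)
            ratios.append((spec.psd[:, mask].mean()))
        # doubled amplitude -> ~4x source band power over the pink floor
        assert ratios[1] / ratios[0] > 2.0

    def test_coherence_delta_raises_theta_band_coherence(self):
        eff = sd.EffectSpec("theta", coherence_delta=0.2)
        model = sd.default_study_model(3, duration=120, subject_jitter=False)
        pre = sd.generate_study_recording(model, eff, "Pre-BB")
        post = sd.generate_study_recording(model, eff, "Post-BB")
        iu = np.triu_indices(14, k=1)
        pre_c = band_coherence_matrix(pre, BANDS["theta"]).values[iu].mean()
        post_c = band_coherence_matrix(post, BANDS["theta"]).values[iu].mean()
        assert post_c > pre_c + 0.1

    def test_null_effect_paired_test_rejects_at_nominal_rate(self):
        """With no planted effect, Pre/Post theta power differs only by
        estimation noise, so the paired test's rejection rate stays near
        its nominal level."""
        reps, n_subj = 40, 20
        rejections = 0
        for rep in range(reps):
            pre_p, post_p = [], []
            for subj in range(n_subj):
                model = sd.default_study_model(
                    rep * 1000 + subj, duration=30)
                for state, store in (("Pre-BB", pre_p), ("Post-BB", post_p)):
                    rec = sd.generate_study_recording(model, None, state)
                    spec = welch_psd(rec)
                    store.append(relative_band_power(
                        spec, BANDS["theta"]).mean())
            if paired_t(post_p, pre_p).p_raw < 0.05:
                rejections += 1
        assert rejections / reps <= 0.20  # ~4 sigma above the nominal 0.05

    def test_planted_theta_power_effect_is_detected(self):
        """power_delta = 2 in theta must be recovered by the paired test on
        relative theta power in at least 80% of replicates at n = 20."""
        eff = sd.EffectSpec("theta", power_delta=2.0)
        reps, n_subj = 25, 20
        detections = 0
        for rep in range(reps):
            pre_p, post_p = [], []
            for subj in range(n_subj):
                model = sd.default_study_model(
                    50_000 + rep * 1000 + subj, duration=30)
                for state, store in (("Pre-BB", pre_p), ("Post-BB", post_p)):
                    rec = sd.generate_study_recording(model, eff, state)
                    spec = welch_psd(rec)
                    store.append(relative_band_power(
                        spec, BANDS["theta"]).mean())
            res = paired_t(post_p, pre_p)
            if res.p_raw < 0.05 and res.statistic > 0:
                detections += 1
        assert detections / reps >= 0.8


class TestStimulus:
    def test_alpha_beat_envelope_peaks_at_10_hz(self):
        spec = sd.StimulusSpec(f_left=400.0, f_right=410.0)
        wave = sd.generate_bb_stimulus(spec)
        assert sd.detect_beat_frequency(wave, spec.fs_audio) == \
            pytest.approx(10.0, abs=0.5)

    def test_gamma_beat_envelope_peaks_at_30_hz(self):
        spec = sd.StimulusSpec(f_left=400.0, f_right=430.0)
        wave = sd.generate_bb_stimulus(spec)
        assert sd.detect_beat_frequency(wave, spec.fs_audio) == \
            pytest.approx(30.0, abs=0.5)

    def test_equal_carriers_have_no_beat(self):
        spec = sd.StimulusSpec(f_left=400.0, f_right=400.0)
        wave = sd.generate_bb_stimulus(spec)
        assert sd.detect_beat_frequency(wave, spec.fs_audio) == 0.0

    def test_unit_amplitude_sinusoids(self):
        spec = sd.StimulusSpec()
        wave = sd.generate_bb_stimulus(spec)
        assert wave.shape[0] == 2
        assert np.abs(wave).max() <= 1.0
        assert np.abs(wave).max() > 0.99

    def test_aliasing_carrier_rejected(self):
        with pytest.raises(ValueError):
            sd.StimulusSpec(f_left=400.0, f_right=410.0, fs_audio=500.0)


class TestStudySimulation:
    def test_recording_stream_is_deterministic(self):
        cfg = sd.StudyConfig(n_per_group=1, groups=("A",),
                             states=("Pre-BB",), duration=32, seed=9)
        a = next(iter(sd.iter_study_recordings(cfg)))
        b = next(iter(sd.iter_study_recordings(cfg)))
        assert np.array_equal(a.data, b.data)
        assert a.subject_id == "A01" and a.group == "A"

    def test_behavior_effect_group_improves_post(self):
        cfg = sd.StudyConfig(n_per_group=20, duration=32, seed=2,
                             effect_group="A", behavior_boost=0.08)
        sessions = sd.simulate_behavior(cfg)
        from bbnet.behavior_scoring import score_session
        scores = {}
        for s in sessions:
            scores.setdefault((s.subject_id[0], s.state), []).append(
                score_session(s)[0])
        a_gain = np.mean(scores[("A", "Post-BB")]) - \
            np.mean(scores[("A", "Pre-BB")])
        b_gain = np.mean(scores[("B", "Post-BB")]) - \
            np.mean(scores[("B", "Pre-BB")])
        assert a_gain > b_gain

    def test_invalid_effect_band_rejected(self):
        with pytest.raises(ValueError):
            sd.EffectSpec("delta")
        with pytest.raises(ValueError):
            sd.EffectSpec("theta", power_delta=0.0)

    def test_model_validation(self):
        src = sd.SharedSource((4.0, 8.0), 5.0, tuple(np.ones(14)), 0.5)
        with pytest.raises(ValueError):
            sd.SourceMixModel((src,), noise_sd=0.0)
        with pytest.raises(ValueError):
            sd.SourceMixModel((src,), fs=10.0)  # below 2x source frequency
        bad = sd.SharedSource((4.0, 8.0), 5.0, (1.0, 1.0), 0.5)
        with pytest.raises(ValueError):
            sd.SourceMixModel((bad,))
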