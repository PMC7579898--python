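import numpy as np
import pytest

import pdscreen as pds
from pdscreen.errors import InsufficientVoicingError, TooShortError
from pdscreen.io_formats import VOICE_FEATURE_NAMES
from pdscreen.voice import (apq, dda, ddp, jitter_percent, rap,
                            shimmer_percent)


class TestPreprocess:
    def test_truncation_10s_to_6s(self, vowel_default):
        rec, _ = vowel_default
        out = pds.preprocess_voice(rec)
        assert out.duration == pytest.approx(6.0, abs=0.01)

    def test_output_rate_and_nyquist_margin(self, vowel_preprocessed):
        out, _ = vowel_preprocessed
        assert out.fs == 22050
        assert out.fs > 2 * 8000  # Nyquist margin for the 8 kHz band edge

    def test_peak_normalized(self, vowel_preprocessed):
        out, _ = vowel_preprocessed
        assert np.max(np.abs(out.samples)) == pytest.approx(1.0)

    def test_band_edge_attenuation(self):
        """10 kHz tone attenuated >= 20 dB relative to 1 kHz at the filter."""
        fs = 44100
        t = np.arange(0, 6, 1 / fs)
        from scipy import signal as sps
        sos = sps.butter(4, [50, 8000], btype="bandpass", fs=fs, output="sos")
        out1 = sps.sosfiltfilt(sos, np.sin(2 * np.pi * 1000 * t))
        out10 = sps.sosfiltfilt(sos, np.sin(2 * np.pi * 10000 * t))
        ratio_db = 20 * np.log10(np.std(out1) / np.std(out10))
        assert ratio_db >= 20

    def test_too_short_raises(self):
        rec = pds.VoiceRecording(np.random.default_rng(0).normal(
            size=3 * 44100), 44100)
        with pytest.raises(TooShortError, match="discard"):
            pds.preprocess_voice(rec)


class TestF0Track:
    def test_pure_tone_150hz(self):
        t = np.arange(0, 2, 1 / 22050)
        rec = pds.VoiceRecording(np.sin(2 * np.pi * 150 * t), 22050)
        track = pds.estimate_f0_track(rec)
        f0 = track.f0[track.voiced]
        assert len(f0) > 0
        assert np.all(np.abs(f0 - 150) <= 1.0)

    def test_silence_unvoiced(self):
        rec = pds.VoiceRecording(np.zeros(22050), 22050)
        track = pds.estimate_f0_track(rec)
        assert track.n_voiced == 0
        assert len(track.cycle_periods) == 0

    def test_period_matches_generator(self, vowel_preprocessed, vowel_track):
        _, truth = vowel_preprocessed
        tw = truth.in_window(1.0, 7.0)
        mean_t = vowel_track.cycle_periods.mean()
        assert mean_t == pytest.approx(tw.periods.mean(), rel=0.005)

    def test_f0_equals_inverse_period(self, vowel_track):
        v = vowel_track.voiced
        np.testing.assert_allclose(vowel_track.f0[v],
                                   1.0 / vowel_track.period[v])


class TestVoiceFeatures:
    def test_22_named_values_in_canonical_order(self, vowel_features):
        assert len(vowel_features) == 22
        assert vowel_features.names == VOICE_FEATURE_NAMES

    def test_f0_ordering_invariant(self, vowel_features):
        d = vowel_features.as_dict()
        assert d["MDVP:Flo(Hz)"] <= d["MDVP:Fo(Hz)"] <= d["MDVP:Fhi(Hz)"]

    def test_normalized_measures_in_unit_interval(self, vowel_features):
        d = vowel_features.as_dict()
        assert 0 <= d["RPDE"] <= 1
        assert 0 <= d["DFA"] <= 1
        assert 0 <= d["PPE"] <= 1

    def test_perfectly_periodic_tone_near_zero_perturbation(self):
        rec, _ = pds.simulate_vowel(pds.VowelSimSpec(
            f0=150, jitter_pct=0, shimmer_pct=0, hnr_db=None, seed=0))
        track = pds.estimate_f0_track(pds.preprocess_voice(rec))
        assert jitter_percent(track.cycle_periods) < 0.01
        assert shimmer_percent(track.cycle_amplitudes) < 0.01

    def test_jitter_recovered_within_tolerance(self, vowel_preprocessed,
                                               vowel_track):
        _, truth = vowel_preprocessed
        tw = truth.in_window(1.0, 7.0)
        measured = jitter_percent(vowel_track.cycle_periods)
        expected = jitter_percent(tw.periods)
        assert measured == pytest.approx(expected, abs=0.2)

    def test_ddp_is_three_rap_identity(self, vowel_track):
        T = vowel_track.cycle_periods
        assert ddp(T) == pytest.approx(3 * rap(T), abs=1e-6)
        # and on an arbitrary positive sequence
        rng = np.random.default_rng(3)
        T2 = 0.006 + 0.0001 * rng.normal(size=100)
        assert ddp(T2) == pytest.approx(3 * rap(T2), abs=1e-9)

    def test_dda_is_three_apq3_identity(self, vowel_track):
        A = vowel_track.cycle_amplitudes
        assert dda(A) == pytest.approx(3 * apq(A, 3), abs=1e-9)

    def test_scaling_invariance_of_perturbation_measures(
            self, vowel_preprocessed, vowel_track):
        rec, _ = vowel_preprocessed
        scaled = pds.VoiceRecording(rec.samples * 5.0, rec.fs)
        track2 = pds.estimate_f0_track(scaled)
        assert (jitter_percent(track2.cycle_periods)
                == pytest.approx(jitter_percent(vowel_track.cycle_periods),
                                 abs=1e-9))
        assert (shimmer_percent(track2.cycle_amplitudes)
                == pytest.approx(
                    shimmer_percent(vowel_track.cycle_amplitudes), abs=1e-9))

    def test_insufficient_voicing_raises(self):
        rng = np.random.default_rng(0)
        rec = pds.VoiceRecording(rng.normal(size=22050), 22050)
        with pytest.raises(InsufficientVoicingError):
            pds.compute_voice_features(rec)


class TestCrossTalk:
    """Jitter and shimmer are measured from separate cycle sequences; each
    parameter must not masquerade as the other (below 10% of effect size)."""

    def test_amplitude_perturbation_does_not_leak_into_jitter(self):
        rec, _ = pds.simulate_vowel(pds.VowelSimSpec(
            jitter_pct=0, shimmer_pct=3.0, hnr_db=None, seed=9))
        track = pds.estimate_f0_track(rec)
        assert jitter_percent(track.cycle_periods) < 0.1 * 3.0

    def test_period_perturbation_does_not_leak_into_shimmer(self):
        rec, _ = pds.simulate_vowel(pds.VowelSimSpec(
            jitter_pct=2.0, shimmer_pct=0, hnr_db=None, seed=9))
        track = pds.estimate_f0_track(rec)
        assert shimmer_percent(track.cycle_amplitudes) < 0.1 * 2.0


class TestMonotonicity:
    def test_jitter_strictly_increasing_in_generator_parameter(self):
        vals = []
        for j in (0.0, 1.0, 2.0, 3.0, 4.0):
            rec, _ = pds.simulate_vowel(pds.VowelSimSpec(jitter_pct=j, seed=11))
            track = pds.estimate_f0_track(pds.preprocess_voice(rec))
            vals.append(jitter_percent(track.cycle_periods))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_hnr_decreases_with_noise_level(self):
        vals = []
        for target in (30.0, 20.0, 10.0, 5.0):
            rec, _ = pds.simulate_vowel(pds.VowelSimSpec(hnr_db=target, seed=3))
            track = pds.estimate_f0_track(pds.preprocess_voice(rec))
            r = np.clip(track.ac_peak[track.voiced], 1e-6, 1 - 1e-6)
            vals.append(float(np.mean(10 * np.log10(r / (1 - r)))))
        assert all(b < a for a, b in zip(vals, vals[1:]))
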