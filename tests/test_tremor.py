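import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pdscreen as pds
from pdscreen.errors import InsufficientDataError, ParameterError
from pdscreen.tremor import CATEGORIES, TremorQuantitative


def _rec(x, fs=100.0):
    z = np.zeros_like(x)
    return pds.AccelRecording(np.asarray(x, float), z.copy(), z.copy(), fs=fs)


class TestDetrend:
    def test_constant_offset_removed(self):
        rec = pds.AccelRecording(np.zeros(500), np.zeros(500),
                                 np.full(500, 9.81), fs=100)
        out = pds.detrend(rec, 100)
        assert np.allclose(out.z, 0.0, atol=1e-12)

    def test_piecewise_offset_removed(self):
        x = np.concatenate([np.full(100, 1.0), np.full(100, 2.0)])
        out = pds.detrend(_rec(x), 100)
        assert np.allclose(out.x, 0.0, atol=1e-12)

    def test_window_means_zero_for_sine_plus_offset(self):
        t = np.arange(1000) / 100
        x = np.sin(2 * np.pi * 5 * t) + 3.0
        out = pds.detrend(_rec(x), 100)
        for s in range(0, 1000, 100):
            assert abs(out.x[s:s + 100].mean()) < 1e-9

    def test_partial_final_window_zero_mean(self):
        x = np.arange(250, dtype=float)
        out = pds.detrend(_rec(x), 100)
        assert abs(out.x[200:].mean()) < 1e-9

    def test_window_too_small(self):
        with pytest.raises(ParameterError):
            pds.detrend(_rec(np.zeros(10)), 1)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(10, 300))
        once = pds.detrend(_rec(x), 50)
        twice = pds.detrend(once, 50)
        np.testing.assert_allclose(twice.x, once.x, atol=1e-9)


class TestBandDecomposition:
    def test_zero_signal_all_bands_zero(self):
        dec = pds.wavelet_band_decompose(_rec(np.zeros(256)))
        for band in (dec.low, dec.rest, dec.postural, dec.residual):
            assert np.allclose(band["x"], 0.0)

    def test_rest_band_captures_5hz(self):
        """>= 80% of band energy of a 5 Hz tone lands in the 3-6 Hz band
        (checked against the raw band-energy partition, FFT-equivalently)."""
        t = np.arange(0, 10, 0.01)
        dec = pds.wavelet_band_decompose(_rec(np.sin(2 * np.pi * 5 * t)))
        energies = {name: np.sum(getattr(dec, name)["x"] ** 2)
                    for name in ("low", "rest", "postural", "residual")}
        total = sum(energies.values())
        assert energies["rest"] / total >= 0.80
        # cross-check against an FFT oracle: nearly all input energy is at 5 Hz
        spec = np.abs(np.fft.rfft(np.sin(2 * np.pi * 5 * t))) ** 2
        freqs = np.fft.rfftfreq(1000, 0.01)
        assert spec[(freqs >= 3) & (freqs <= 6)].sum() / spec.sum() > 0.999

    def test_low_band_dominates_1hz(self):
        t = np.arange(0, 10, 0.01)
        dec = pds.wavelet_band_decompose(_rec(np.sin(2 * np.pi * 1 * t)))
        energies = [np.sum(getattr(dec, n)["x"] ** 2)
                    for n in ("low", "rest", "postural")]
        assert np.argmax(energies) == 0

    def test_energy_conserving_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=777)
        dec = pds.wavelet_band_decompose(_rec(x))
        np.testing.assert_allclose(dec.reconstruct("x"), x, atol=1e-8)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            pds.wavelet_band_decompose(_rec(np.zeros(8)))


class TestTremorFeatures:
    def test_48_values_with_all_categories(self):
        rec, _ = pds.simulate_tremor(pds.TremorSimSpec(updrs=2, seed=0))
        fv = pds.extract_tremor_features(pds.detrend(rec, 100))
        assert len(fv) == 48
        assert len(set(fv.names)) == 48

    def test_24_values_with_top8_category_slots(self):
        names = pds.top_category_features(8)
        assert len(names) == 24
        rec, _ = pds.simulate_tremor(pds.TremorSimSpec(updrs=2, seed=0))
        fv = pds.extract_tremor_features(pds.detrend(rec, 100))
        assert set(names) <= set(fv.names)

    def test_zero_recording_zero_features(self):
        fv = pds.extract_tremor_features(_rec(np.zeros(200)))
        d = fv.as_dict()
        for cat in ("average_amplitude", "zero_crossing_rate",
                    "tremor_occurrence"):
            assert d[f"x.{cat}.mean"] == 0.0

    def test_freq_at_max_power_5hz(self):
        t = np.arange(0, 10, 0.01)
        fv = pds.extract_tremor_features(_rec(np.sin(2 * np.pi * 5 * t)))
        bin_width = 100 / 20
        assert abs(fv.as_dict()["x.freq_at_max_power.mean"] - 5) <= bin_width

    def test_offset_invariance_after_detrend(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        a = pds.extract_tremor_features(pds.detrend(_rec(x), 100))
        b = pds.extract_tremor_features(pds.detrend(_rec(x + 7.5), 100))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        a = pds.extract_tremor_features(_rec(x)).as_dict()
        b = pds.extract_tremor_features(_rec(2 * x)).as_dict()
        for axis in "xyz":
            key = f"{axis}.average_amplitude.mean"
            assert b[key] == pytest.approx(2 * a[key], rel=1e-9, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            pds.extract_tremor_features(_rec(np.zeros(20)))  # single window
        with pytest.raises(InsufficientDataError):
            pds.extract_tremor_features(_rec(np.zeros(10)))  # below window
        with pytest.raises(ParameterError):
            pds.extract_tremor_features(_rec(np.zeros(200)), categories=())
        with pytest.raises(ParameterError):
            pds.extract_tremor_features(_rec(np.zeros(200)),
                                        categories=("nope",))

    def test_category_subset(self):
        fv = pds.extract_tremor_features(_rec(np.zeros(200)),
                                         categories=CATEGORIES[:2])
        assert len(fv) == 12  # 2 categories x 2 stats x 3 axes


class TestQuantitative:
    def test_zero_signal(self):
        q = pds.estimate_quantitative(_rec(np.zeros(1000)))
        assert q.max_amplitude_cm == 0.0
        assert q.occurrence_pct == 0.0

    def test_harmonic_inversion_1cm(self, sine_recording):
        """a = (2 pi f)^2 d: acceleration amplitude 9.8696 at 5 Hz is 1 cm."""
        q = pds.estimate_quantitative(sine_recording)
        assert q.max_amplitude_cm == pytest.approx(1.0, rel=0.03)
        assert q.occurrence_pct > 95

    def test_constructed_occurrence_fraction(self):
        rec, truth = pds.simulate_tremor(pds.TremorSimSpec(
            updrs=2, occurrence=0.40, seed=5))
        q = pds.estimate_quantitative(pds.detrend(rec, 100))
        assert q.occurrence_pct == pytest.approx(truth.occurrence_pct, abs=5)


class TestUPDRSRule:
    @pytest.mark.parametrize("amp,occ,expected", [
        (0.0, 0.0, 0),
        (0.5, 10.0, 1),
        (2.0, 40.0, 2),
        (5.0, 60.0, 3),
        (12.0, 90.0, 4),
        # disagreement resolved toward the severer grade
        (0.5, 60.0, 3),
        (12.0, 10.0, 4),
    ])
    def test_rule_table(self, amp, occ, expected):
        q = TremorQuantitative(amp, occ)
        assert pds.updrs_from_quantitative(q).level == expected

    @given(st.floats(0, 20), st.floats(0, 100), st.floats(0, 20),
           st.floats(0, 100))
    def test_monotone_in_both_arguments(self, a1, o1, a2, o2):
        lo = pds.updrs_from_quantitative(
            TremorQuantitative(min(a1, a2), min(o1, o2))).level
        hi = pds.updrs_from_quantitative(
            TremorQuantitative(max(a1, a2), max(o1, o2))).level
        assert lo <= hi
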