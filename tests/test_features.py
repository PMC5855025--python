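"""Window segmentation and the 18 spectro-temporal features, each checked
against an independent oracle (hand arithmetic, brute-force scans,
parameter-recovery simulations, closed-form spectra)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import fftconvolve

import edadrive as ed
from edadrive.features import Window
from conftest import peak_scan_oracle


def _window(x, fs=50.0, **kw):
    return Window(np.asarray(x, float), fs, **kw)


class TestSegment:
    def test_two_minute_recording_yields_116_windows(self):
        wins = ed.segment(np.zeros(6000), 50.0)
        assert len(wins) == 116
        assert all(w.samples.size == 250 for w in wins)
        starts = [w.start_s for w in wins]
        np.testing.assert_allclose(np.diff(starts), 1.0)

    def test_exactly_one_window(self):
        assert len(ed.segment(np.zeros(250), 50.0)) == 1

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ed.segment(np.zeros(245), 50.0)
        with pytest.raises(ValueError):
            ed.segment(np.zeros(500), 50.0, win_s=5, overlap_s=5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=250, max_value=4000))
    def test_count_matches_closed_form(self, n):
        wins = ed.segment(np.zeros(n), 50.0)
        assert len(wins) == (n - 250) // 50 + 1


class TestBasicStats:
    def test_hand_arithmetic(self):
        w = _window([1.0, 2.0, 3.0])
        f1, f2, f3, f4, f5 = ed.basic_stats(w, total_task_s=120.0)
        assert f1 == 2.0
        assert abs(f2 - 2.0 / 3.0) < 1e-12
        assert abs(f3 - 0.05) < 1e-12
        assert f4 == 3.0
        assert abs(f5 - 14.0 / 3.0) < 1e-12

    def test_zero_and_constant_windows(self):
        assert ed.basic_stats(_window(np.zeros(50)), 10.0) == (0, 0, 0, 0, 0)
        f1, f2, _, _, f5 = ed.basic_stats(_window(np.full(50, 2.0)), 10.0)
        assert f2 == 0.0 and f5 == 4.0

    def test_invalid_task_time(self):
        with pytest.raises(ValueError):
            ed.basic_stats(_window([1, 2, 3]), 0.0)


class TestDetectPeaks:
    def test_constant_window_has_no_peaks(self):
        scan = ed.detect_peaks(_window(np.full(250, 1.0)))
        assert scan.n_peaks == 0 and scan.sum_amplitudes == 0.0
        assert not np.any(scan.q2)

    def test_single_scr_detected_with_amplitude(self):
        fs = 50.0
        k = ed.bateman_kernel(1.0, 3.75, fs)
        d = np.zeros(250)
        d[50] = 60.0 * fs  # large SCR so max Q2 > 1 at the printed threshold
        scr = fftconvolve(d, k)[:250] / fs
        scan = ed.detect_peaks(_window(scr), threshold=1.0)
        assert scan.q2.max() > 1.0
        assert scan.n_peaks == 1
        assert scan.sum_amplitudes == pytest.approx(scr.max())

    def test_two_separated_scrs(self):
        # two onsets 6 s apart; the rises cross the threshold, the slow
        # decays do not, so the scan finds exactly two regions
        fs = 50.0
        k = ed.bateman_kernel(1.0, 3.75, fs)
        d = np.zeros(500)
        d[50] = d[350] = 60.0 * fs
        sig = fftconvolve(d, k)[:500] / fs
        scan = ed.detect_peaks(Window(sig, fs), threshold=1.0)
        assert scan.n_peaks == 2

    def test_matches_bruteforce_oracle_on_random_windows(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(5, 120)
            p = rng.normal(size=n)
            thr = rng.uniform(0.2, 3.0)
            scan = ed.detect_peaks(_window(p), threshold=thr)
            n_ref, s_ref = peak_scan_oracle(list(p), thr)
            assert scan.n_peaks == n_ref
            assert scan.sum_amplitudes == pytest.approx(s_ref)

    def test_q2_weighting_identity(self):
        rng = np.random.default_rng(2)
        scan = ed.detect_peaks(_window(rng.normal(size=100)))
        np.testing.assert_allclose(scan.q2, 1.3 * scan.q0 + 1.1 * scan.q1)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            ed.detect_peaks(_window([1, 2, 3, 4]))


class TestSTFTBands:
    def test_white_noise_flat_across_bands(self):
        means = np.zeros(4)
        for s in range(100):
            x = np.random.default_rng(s).normal(size=250)
            means += ed.stft_band_features(_window(x))
        means /= 100
        assert means.max() / means.min() < 1.2

    def test_low_tone_concentrates_in_band_one(self):
        t = np.arange(250) / 50.0
        bands = ed.stft_band_features(_window(np.sin(2 * np.pi * 3.0 * t)))
        assert bands[0] >= 10 * bands[1:].max()

    def test_zero_window(self):
        np.testing.assert_array_equal(
            ed.stft_band_features(_window(np.zeros(250))), 0.0)


class TestFractalDimensions:
    def test_higuchi_line_near_one(self):
        assert abs(ed.higuchi_fd(np.arange(250) / 50.0) - 1.0) < 0.05

    def test_higuchi_white_noise_near_two(self):
        vals = [ed.higuchi_fd(np.random.default_rng(s).normal(size=250))
                for s in range(50)]
        assert abs(np.mean(vals) - 2.0) < 0.15

    def test_higuchi_scale_invariant(self):
        x = np.random.default_rng(3).normal(size=300)
        assert abs(ed.higuchi_fd(x) - ed.higuchi_fd(3.0 * x)) < 1e-9

    def test_higuchi_kmax_guard(self):
        with pytest.raises(ValueError):
            ed.higuchi_fd(np.arange(10.0), kmax=8)

    def test_katz_monotone_line_exactly_one(self):
        assert ed.katz_fd(np.linspace(0.0, 2.0, 100)) == 1.0

    def test_katz_constant_is_one_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert ed.katz_fd(np.full(50, 1.5)) == 1.0

    def test_katz_triangle_wave_against_direct_formula(self):
        x = np.abs(np.arange(100) % 20 - 10).astype(float)
        L = np.abs(np.diff(x)).sum()
        d = np.max(np.abs(x - x[0]))
        expect = np.log10(99) / (np.log10(99) + np.log10(d / L))
        assert ed.katz_fd(x) == pytest.approx(expect)


class TestARCoefficients:
    @staticmethod
    def _simulate_ar(coefs, n, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=n)
        x = np.zeros(n)
        p = len(coefs)
        for i in range(p, n):
            x[i] = np.dot(coefs, x[i - p:i][::-1]) + e[i]
        return x

    def test_ar1_recovery(self):
        x = self._simulate_ar([0.5], 20000, seed=0)
        a = ed.ar_coefficients(x, order=5)
        assert abs(a[0] - 0.5) < 0.05
        assert np.max(np.abs(a[1:])) < 0.1

    def test_white_noise_coefficients_small(self):
        vals = [np.max(np.abs(ed.ar_coefficients(
            np.random.default_rng(s).normal(size=500), 5)))
            for s in range(50)]
        assert np.mean(vals) < 0.1

    def test_ar5_recovery(self):
        coefs = [0.5, -0.3, 0.2, -0.1, 0.05]
        x = self._simulate_ar(coefs, 5000, seed=1)
        a = ed.ar_coefficients(x, order=5)
        assert np.max(np.abs(a - coefs)) < 0.05

    def test_order_guard_and_constant_window(self):
        with pytest.raises(ValueError):
            ed.ar_coefficients(np.arange(4.0), order=5)
        np.testing.assert_array_equal(
            ed.ar_coefficients(np.full(100, 2.0), 5), 0.0)


class TestExtractFeatures:
    def test_all_18_fields_in_order(self):
        rng = np.random.default_rng(0)
        w = _window(rng.normal(size=250), subject_id="s1", condition="phone")
        fv = ed.extract_features(w, total_task_s=120.0, peak_threshold=0.5)
        assert fv.values.shape == (18,)
        assert fv.label == "phone" and fv.subject_id == "s1"
        # spot-check the layout against the individual operations
        assert fv.values[0] == pytest.approx(np.mean(w.samples))
        assert fv.values[3] == pytest.approx(np.max(w.samples))
        assert fv.values[11] == pytest.approx(ed.higuchi_fd(w.samples))
        assert fv.values[12] == pytest.approx(ed.katz_fd(w.samples))
        np.testing.assert_allclose(fv.values[13:],
                                   ed.ar_coefficients(w.samples, 5))

    def test_all_zero_window_edge_case(self):
        with pytest.warns(RuntimeWarning):
            fv = ed.extract_features(_window(np.zeros(250)), 120.0)
        np.testing.assert_array_equal(fv.values[:11], 0.0)
        assert fv.values[11] == 1.0 and fv.values[12] == 1.0   # flat-curve FDs
        np.testing.assert_array_equal(fv.values[13:], 0.0)

    def test_deterministic(self):
        x = np.random.default_rng(5).normal(size=250)
        a = ed.extract_features(_window(x), 120.0)
        b = ed.extract_features(_window(x), 120.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_table_skips_bad_windows_with_warning(self):
        good = _window(np.random.default_rng(0).normal(size=250))
        bad = _window(np.full(3, 1.0))   # too short for every feature
        with pytest.warns(UserWarning, match="skipped"):
            df = ed.extract_table([good, bad], 120.0)
        assert len(df) == 1
        assert not df[list(ed.FEATURE_NAMES)].isna().any().any()


class TestCohortBookkeeping:
    def test_window_count_matches_closed_form(self, pipeline_result_small):
        df = pipeline_result_small.features
        # 3 subjects x 3 conditions x 116 windows per 120 s recording
        assert len(df) == 3 * 3 * 116

    def test_peak_count_monotone_with_distraction(self, pipeline_result_small):
        means = pipeline_result_small.features.groupby("condition")["f6"].mean()
        assert means["normal"] < means["phone"] < means["text"]


class TestWVD:
    def test_tone_ridge_at_normalized_frequency(self):
        fs, f0 = 50.0, 5.0
        x = np.sin(2 * np.pi * f0 * np.arange(512) / fs)
        tf = ed.wvd_spectrogram(x, fs)
        ridge = tf.freq_axis[np.argmax(tf.matrix.mean(axis=0))]
        assert abs(ridge - 2 * f0 / fs) < 0.02

    def test_energy_conservation(self):
        from scipy.signal import hilbert

        fs = 50.0
        x = np.sin(2 * np.pi * 4.0 * np.arange(512) / fs)
        tf = ed.wvd_spectrogram(x, fs)
        z_energy = np.sum(np.abs(hilbert(x)) ** 2)
        assert abs(tf.total_energy() - z_energy) < 0.05 * z_energy

    def test_zero_signal_zero_map(self):
        tf = ed.wvd_spectrogram(np.zeros(128), 50.0)
        assert not np.any(tf.matrix)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ed.wvd_spectrogram(np.zeros(32), 50.0)
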