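"""Signal primitives against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import cspdetect as cd
from cspdetect.errors import DetectionError, ParameterError


class TestLocateArtifact:
    def test_trigger_passthrough(self):
        t = cd.EMGTrial(np.zeros(1000) + 0.1, 5000.0, trigger_idx=500)
        assert cd.locate_tms_artifact(t) == 500

    def test_unique_spike_found(self):
        x = np.zeros(1000)
        x[500] = 8.0
        t = cd.EMGTrial(x, 5000.0)
        assert cd.locate_tms_artifact(t) == 500

    def test_constant_signal_without_trigger_fails(self):
        with pytest.raises(DetectionError):
            cd.locate_tms_artifact(cd.EMGTrial(np.ones(100), 5000.0))

    def test_recovers_construction_index_on_synthetic_trials(self):
        fs = 5000.0
        tol = round(0.5e-3 * fs)
        for seed in range(50):
            trial, _ = cd.generate_trial(cd.GenerationParams(seed=seed))
            untriggered = cd.EMGTrial(trial.samples, fs, trial_id=trial.trial_id)
            assert abs(cd.locate_tms_artifact(untriggered) - trial.trigger_idx) <= tol


class TestExtractFrame:
    def test_window_arithmetic_at_5khz(self):
        t = cd.EMGTrial(np.random.default_rng(0).normal(size=4000), 5000.0)
        f = cd.extract_frame(t, 1000)
        assert (f.start_idx, f.end_idx) == (700, 3100)
        assert f.artifact_offset == 300

    def test_window_arithmetic_at_1khz(self):
        t = cd.EMGTrial(np.random.default_rng(0).normal(size=600), 1000.0)
        f = cd.extract_frame(t, 100)
        assert (f.start_idx, f.end_idx) == (40, 520)

    def test_insufficient_prepulse_clips_with_warning(self):
        t = cd.EMGTrial(np.random.default_rng(0).normal(size=4000), 5000.0)
        with pytest.warns(UserWarning):
            f = cd.extract_frame(t, 100)
        assert f.start_idx == 0

    def test_artifact_too_close_to_end_fails(self):
        t = cd.EMGTrial(np.random.default_rng(0).normal(size=4000), 5000.0)
        with pytest.raises(DetectionError):
            cd.extract_frame(t, 3990)

    def test_reextraction_is_idempotent(self):
        t = cd.EMGTrial(np.random.default_rng(0).normal(size=4000), 5000.0)
        a = cd.extract_frame(t, 1000)
        b = cd.extract_frame(t, 1000)
        assert (a.start_idx, a.artifact_idx, a.end_idx) == (
            b.start_idx,
            b.artifact_idx,
            b.end_idx,
        )
        assert (a.samples == b.samples).all()


class TestButterworth:
    def test_highpass_rejects_dc(self):
        out = cd.butterworth_filter(np.ones(2000), 0.016, "highpass")
        assert np.abs(out).max() < 1e-6

    def test_lowpass_passes_dc(self):
        out = cd.butterworth_filter(np.ones(2000), 0.016, "lowpass")
        assert np.abs(out[100:-100] - 1.0).max() < 1e-6

    def test_slow_sine_attenuation_matches_frequency_response(self):
        """5 Hz sine vs the designed filter's |H|^2 (forward-backward)."""
        fs = 5000.0
        sos = sps.butter(2, 0.016, btype="highpass", output="sos")
        w, h = sps.sosfreqz(sos, worN=[5.0], fs=fs)
        expected = np.abs(h[0]) ** 2  # filtfilt squares the magnitude
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = cd.butterworth_filter(x, 0.016, "highpass")
        interior = slice(2500, -2500)
        ratio = np.sqrt((y[interior] ** 2).mean() / (x[interior] ** 2).mean())
        assert ratio == pytest.approx(expected, rel=0.2)
        assert 1 / ratio >= 20

    def test_double_highpass_barely_changes_white_noise(self):
        x = np.random.default_rng(0).normal(size=5000)
        once = cd.butterworth_filter(x, 0.016, "highpass")
        twice = cd.butterworth_filter(once, 0.016, "highpass")
        interior = slice(500, -500)
        r1 = np.sqrt((once[interior] ** 2).mean())
        r2 = np.sqrt((twice[interior] ** 2).mean())
        assert abs(r2 - r1) / r1 < 0.05

    def test_too_short_input_fails(self):
        with pytest.raises(ParameterError):
            cd.butterworth_filter(np.ones(5), 0.016, "highpass")


class TestAbsDerivative:
    def test_direct_formula(self):
        assert cd.abs_derivative([0, 1, -1]).tolist() == [1, 2]

    def test_constant_gives_zeros(self):
        assert not cd.abs_derivative(np.full(50, 3.3)).any()

    def test_too_short_fails(self):
        with pytest.raises(ParameterError):
            cd.abs_derivative([1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    def test_triangle_inequality_and_oracle(self, xs):
        x = np.array(xs)
        out = cd.abs_derivative(x)
        brute = np.array([abs(x[i + 1] - x[i]) for i in range(len(x) - 1)])
        assert np.array_equal(out, brute)
        assert out.sum() >= abs(x[-1] - x[0]) - 1e-9 * max(1, out.sum())


class TestMovingAverage:
    def test_direct_example(self):
        out = cd.moving_average([0, 0, 3, 0, 0], 3)
        assert np.isnan(out[:2]).all()
        assert out[2:].tolist() == [1, 1, 1]

    def test_constant_identity(self):
        out = cd.moving_average(np.full(40, 2.5), 7)
        assert np.allclose(out[6:], 2.5)

    def test_too_short_fails(self):
        with pytest.raises(ParameterError):
            cd.moving_average([1.0, 2.0], 3)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=30,
            max_size=120,
        ),
        st.integers(min_value=1, max_value=30),
    )
    def test_brute_force_oracle(self, xs, n):
        x = np.array(xs)
        out = cd.moving_average(x, n)
        assert np.isnan(out[: n - 1]).all()
        for i in range(n - 1, len(x)):
            assert out[i] == pytest.approx(
                sum(x[i - n + 1 : i + 1]) / n, abs=1e-10, rel=1e-10
            )


class TestSpectrogram:
    def test_zero_signal_gives_zero_power(self):
        _, _, psd, summed = cd.spectrogram(np.zeros(2100), 20)
        assert not psd.any() and not summed.any()

    def test_sine_summed_power_stationary(self):
        t = np.arange(2100) / 5000.0
        x = np.sin(2 * np.pi * 200.0 * t)
        _, _, _, summed = cd.spectrogram(x, 10, fs=5000.0)
        interior = summed[1:-1]
        assert interior.max() / interior.min() < 1.05

    def test_segment_geometry_from_overlap_formula(self):
        _, times, psd, _ = cd.spectrogram(np.random.default_rng(0).normal(size=2100), 20)
        seg_len = (2 * 2100) // 21
        assert seg_len == 200
        # hop = 100 -> segment count 1 + (2100 - 200) // 100 = 20
        assert psd.shape[1] == 20

    def test_too_short_frame_fails(self):
        with pytest.raises(ParameterError):
            cd.spectrogram(np.zeros(20), 10)


class TestPrepulseStats:
    def _trial_from(self, segment, fs=5000.0, tail=200):
        samples = np.concatenate([segment, np.zeros(tail)])
        samples[len(segment) + 10] = 8.0
        return cd.EMGTrial(samples, fs), len(segment) + 10

    def test_sine_negative_peaks_equal_amplitude(self):
        fs = 5000.0
        t = np.arange(int(fs * 0.5)) / fs
        seg = 0.2 * np.sin(2 * np.pi * 40 * t)
        trial, a_idx = self._trial_from(seg)
        stats = cd.prepulse_stats(trial, a_idx)
        assert stats.mean_negative_peak == pytest.approx(-0.2, rel=0.02)
        assert stats.n_peaks >= 10

    def test_constant_segment_fails(self):
        trial, a_idx = self._trial_from(np.zeros(2000))
        with pytest.raises(DetectionError):
            cd.prepulse_stats(trial, a_idx)

    def test_too_little_prepulse_fails(self):
        trial, a_idx = self._trial_from(np.random.default_rng(0).normal(size=100))
        with pytest.raises(DetectionError):
            cd.prepulse_stats(trial, a_idx)

    def test_matches_brute_force_peak_scan(self):
        p = cd.GenerationParams(seed=21)
        seg = cd.generate_background(400.0, p, seed=21)
        trial, a_idx = self._trial_from(seg)
        stats = cd.prepulse_stats(trial, a_idx)
        guard = cd.ms_to_samples(2.0, 5000.0)
        inner = trial.samples[: a_idx - guard]
        brute = [
            inner[i]
            for i in range(1, len(inner) - 1)
            if inner[i] < inner[i - 1] and inner[i] < inner[i + 1] and inner[i] < 0
        ]
        assert stats.mean_negative_peak == pytest.approx(
            np.mean(brute), rel=0.10
        )

    def test_baseline_stable_across_seeds(self):
        peaks = []
        for seed in range(50):
            p = cd.GenerationParams(seed=seed)
            seg = cd.generate_background(400.0, p, seed=seed)
            trial, a_idx = self._trial_from(seg)
            peaks.append(cd.prepulse_stats(trial, a_idx).mean_negative_peak)
        peaks = np.array(peaks)
        assert abs(peaks.std() / peaks.mean()) < 0.15

    def test_prepulse_cap_limits_segment(self):
        p = cd.GenerationParams(seed=2)
        seg = cd.generate_background(400.0, p, seed=2)
        trial, a_idx = self._trial_from(seg)
        capped = cd.prepulse_stats(
            trial, a_idx, cd.AnalysisConfig(prepulse_max_ms=60.0)
        )
        full = cd.prepulse_stats(trial, a_idx)
        assert capped.segment[1] - capped.segment[0] == cd.ms_to_samples(60.0, 5000.0)
        assert full.segment[0] == 0
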