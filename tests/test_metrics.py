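"""Closed-form oracles and invariants for the per-trial kinematic metrics."""

import math

import numpy as np
import pytest

from whiskmap import (
    AnalysisParams,
    AngleTrace,
    Trial,
    band_amplitude,
    baseline_angle,
    bilateral_difference,
    binned_angle_change,
    early_peak,
    mean_angle_change,
    movement_latency,
    zero_lag_correlation,
)

from conftest import N_FRAMES, ONSET, const_trace, step_trace


def make_trial(left: np.ndarray, right: np.ndarray) -> Trial:
    return Trial(
        "m1", "s1", 0, (0, 0), (0.0, 2.5), "high",
        AngleTrace(left), AngleTrace(right),
    )


def stim_sinusoid(freq_hz: float, amp: float, phase: float = 0.0) -> np.ndarray:
    """Zero before onset; amp*sin(2*pi*f*t) during stimulation (end-of-frame t)."""
    x = np.zeros(N_FRAMES)
    t = (np.arange(ONSET, N_FRAMES) - ONSET + 1) * 0.002
    x[ONSET:] = amp * np.sin(2 * math.pi * freq_hz * t + phase)
    return x


class TestBaseline:
    def test_constant(self, params):
        assert baseline_angle(const_trace(10.0), params) == 10.0

    def test_two_frame_mean(self, params):
        x = const_trace(0.0)
        x[248], x[249] = 9.0, 11.0
        assert baseline_angle(x, params) == 10.0

    def test_linear_ramp_crossing_zero_at_onset(self, params):
        # angle = 0.1 deg/frame * (frame - 250): frames 248, 249 -> -0.2, -0.1
        x = 0.1 * (np.arange(N_FRAMES) - 250.0)
        assert baseline_angle(x, params) == pytest.approx(-0.15, abs=1e-12)


class TestMeanChange:
    def test_constant_is_zero(self, params):
        assert mean_angle_change(const_trace(7.0), params) == 0.0

    def test_step_at_onset(self, params):
        assert mean_angle_change(step_trace(8.0, ONSET), params) == pytest.approx(8.0)

    def test_whole_period_sinusoid_averages_out(self, params):
        # 10 Hz = 5 whole periods in the 500-ms window; baseline frames are zero
        x = stim_sinusoid(10.0, 6.0)
        assert mean_angle_change(x, params) == pytest.approx(0.0, abs=1e-9)

    def test_equals_mean_of_bins_tiling_the_window(self, params):
        # consistency oracle: 25 bins x 10 frames tile the stimulation window
        rng = np.random.default_rng(3)
        x = rng.normal(0, 5, N_FRAMES)
        p25 = AnalysisParams(n_bins=25)
        assert mean_angle_change(x, params) == pytest.approx(
            binned_angle_change(x, p25).mean(), abs=1e-12
        )


class TestBinnedChange:
    def test_constant(self, params):
        assert np.allclose(binned_angle_change(const_trace(3.0), params), 0.0)

    def test_step_at_onset(self, params):
        assert np.allclose(binned_angle_change(step_trace(8.0, ONSET), params), 8.0)

    def test_step_mid_bin(self, params):
        # step at frame 275 (50 ms): bin 2 (frames 270-279) is half pre, half post
        out = binned_angle_change(step_trace(8.0, 275), params)
        assert np.allclose(out, [0.0, 0.0, 4.0, 8.0, 8.0, 8.0])


class TestLatency:
    def test_step(self, params):
        # step at frame 270 is the 21st stimulation frame -> 42 ms
        assert movement_latency(step_trace(10.0, 270), params) == 42.0

    def test_censored_when_threshold_never_crossed(self, params):
        x = stim_sinusoid(10.0, 3.9)
        assert math.isnan(movement_latency(x, params))

    def test_ramp(self, params):
        # +0.1 deg/frame from onset: first strict >4 deg at frame 290 -> 82 ms
        x = np.zeros(N_FRAMES)
        i = np.arange(250, N_FRAMES)
        x[250:] = (i - 249) / 10.0
        assert movement_latency(x, params) == 82.0

    def test_strict_inequality_at_threshold(self, params):
        assert math.isnan(movement_latency(step_trace(4.0, ONSET), params))

    @pytest.mark.parametrize("thr", [2.0, 4.0, 6.0])
    def test_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(11)
        x = np.cumsum(rng.normal(0, 0.5, N_FRAMES))
        x[:ONSET] = 0.0
        lo = movement_latency(x, AnalysisParams(latency_threshold=thr))
        hi = movement_latency(x, AnalysisParams(latency_threshold=thr + 1.0))
        if not math.isnan(hi):
            assert lo <= hi


class TestEarlyPeak:
    def test_positive_dominates(self, params):
        x = const_trace(0.0)
        x[260], x[280] = 7.0, -3.0
        assert early_peak(x, params) == 7.0

    def test_negative_dominates(self, params):
        x = const_trace(0.0)
        x[260], x[280] = -9.0, 5.0
        assert early_peak(x, params) == -9.0

    @pytest.mark.parametrize("phase,sign", [(0.0, 1.0), (math.pi, -1.0)])
    def test_sinusoid_sign_of_first_extremum(self, params, phase, sign):
        # one full 10-Hz period inside the 100-ms window
        x = stim_sinusoid(10.0, 6.0, phase)
        peak = early_peak(x, params)
        assert np.sign(peak) == sign
        assert abs(peak) == pytest.approx(6.0, abs=0.05)

    def test_earliest_frame_wins_ties(self, params):
        x = const_trace(0.0)
        x[255], x[260] = -6.0, 6.0
        assert early_peak(x, params) == -6.0


class TestBandAmplitude:
    def fft_window_sinusoid(self, freq_hz, amp):
        x = np.zeros(N_FRAMES)
        t = np.arange(200) / 500.0
        x[300:500] = amp * np.sin(2 * math.pi * freq_hz * t)
        return x

    def test_constant_window_is_zero(self, params):
        assert band_amplitude(const_trace(5.0), params) == 0.0

    def test_on_grid_in_band_sinusoid_recovers_amplitude(self, params):
        x = self.fft_window_sinusoid(10.0, 6.0)
        assert band_amplitude(x, params) == pytest.approx(6.0, abs=1e-9)

    def test_on_grid_out_of_band_sinusoid_is_zero(self, params):
        x = self.fft_window_sinusoid(20.0, 6.0)
        assert band_amplitude(x, params) == pytest.approx(0.0, abs=1e-9)

    def test_mean_invariance(self, params):
        x = self.fft_window_sinusoid(10.0, 6.0)
        assert band_amplitude(x + 100.0, params) == pytest.approx(
            band_amplitude(x, params), abs=1e-9
        )

    def test_phase_invariance_on_grid(self, params):
        a = band_amplitude(self.fft_window_sinusoid(10.0, 6.0), params)
        x = np.zeros(N_FRAMES)
        t = np.arange(200) / 500.0
        x[300:500] = 6.0 * np.sin(2 * math.pi * 10.0 * t + 1.234)
        assert band_amplitude(x, params) == pytest.approx(a, abs=1e-9)

    def test_trapezoid_mode_integrates_in_hz(self):
        p = AnalysisParams(band_mode="trapezoid")
        x = self.fft_window_sinusoid(10.0, 6.0)
        # single 6-deg bin at 10 Hz on the [5, 7.5, 10, 12.5, 15] grid
        assert band_amplitude(x, p) == pytest.approx(2.5 * 6.0, abs=1e-9)

    def test_short_window_raises(self, params):
        with pytest.raises(ValueError, match="FFT window"):
            band_amplitude(np.zeros(400), params)


class TestBilateral:
    def test_identical_traces_difference_zero(self, params):
        x = stim_sinusoid(10.0, 6.0)
        t = make_trial(x, x.copy())
        assert bilateral_difference(t, params) == 0.0
        assert zero_lag_correlation(t, params) == pytest.approx(1.0, abs=1e-9)

    def test_antiphase(self, params):
        x = step_trace(8.0, ONSET) + stim_sinusoid(10.0, 2.0)
        t = make_trial(x, -x)
        assert bilateral_difference(t, params) == pytest.approx(
            2 * mean_angle_change(x, params)
        )
        assert zero_lag_correlation(t, params) == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_flagged_nan(self, params):
        t = make_trial(const_trace(1.0), stim_sinusoid(10.0, 3.0))
        assert math.isnan(zero_lag_correlation(t, params))

    def test_independent_noise_correlation_is_small(self, params):
        # null distribution: |r| < 3/sqrt(250) ~ 0.19 in ~99% of trials
        rng = np.random.default_rng(5)
        hits = 0
        n = 300
        for _ in range(n):
            t = make_trial(rng.normal(0, 1, N_FRAMES), rng.normal(0, 1, N_FRAMES))
            if abs(zero_lag_correlation(t, params)) < 3.0 / math.sqrt(250):
                hits += 1
        assert hits / n >= 0.95


def test_constant_offset_changes_no_metric(params):
    rng = np.random.default_rng(9)
    x = np.cumsum(rng.normal(0, 0.3, N_FRAMES))
    for off in (-40.0, 13.5):
        y = x + off
        assert mean_angle_change(y, params) == pytest.approx(
            mean_angle_change(x, params), abs=1e-9
        )
        assert np.allclose(
            binned_angle_change(y, params), binned_angle_change(x, params), atol=1e-9
        )
        lx, ly = movement_latency(x, params), movement_latency(y, params)
        assert (math.isnan(lx) and math.isnan(ly)) or lx == ly
        assert early_peak(y, params) == pytest.approx(early_peak(x, params), abs=1e-9)
        assert band_amplitude(y, params) == pytest.approx(
            band_amplitude(x, params), abs=1e-9
        )
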