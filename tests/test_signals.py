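"""Unit and property tests for traces, smoothing and the three detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from nocirig.signals import (
    DetectionConfig,
    SignalTrace,
    StimulusEvent,
    StreamingWithdrawalDetector,
    UnitError,
    baseline_level,
    detect_withdrawal_force,
    detect_withdrawal_height,
    detect_withdrawal_reflectance,
    smooth_running_average,
)

from conftest import brute_force_reflectance, make_trace


class TestSignalTrace:
    def test_time_mapping(self):
        tr = make_trace([1.0, 2.0, 3.0], fs=500.0, t0=10.0)
        assert tr.dt == 2.0
        np.testing.assert_allclose(tr.times, [10.0, 12.0, 14.0])
        assert tr.t_end == 14.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(values=[], fs=1000.0),
            dict(values=[1.0, np.nan], fs=1000.0),
            dict(values=[1.0], fs=0.0),
            dict(values=[1.0], fs=1000.0, units="volts"),
        ],
    )
    def test_invalid_traces_rejected(self, kwargs):
        with pytest.raises((ValueError, UnitError)):
            SignalTrace(np.asarray(kwargs.pop("values"), dtype=float), **kwargs)

    def test_stimulus_validation(self):
        with pytest.raises(ValueError):
            StimulusEvent("sonic")
        with pytest.raises(ValueError):
            StimulusEvent("thermal", cutoff=0.0)
        with pytest.raises(ValueError):
            StimulusEvent("thermal", intensity=-1.0)

    def test_detection_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(smooth_window=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(force_drop_fraction=1.5)


class TestSmoothing:
    def test_constant_preserved(self):
        tr = make_trace(np.full(100, 7.5))
        out = smooth_running_average(tr, 27.0)
        np.testing.assert_allclose(out.values, 7.5)
        assert out.units == tr.units and out.fs == tr.fs

    def test_step_response_matches_closed_form(self):
        # step 10 -> 0 at sample s: trailing 27-mean at s+j is 10*(26-j)/27
        s = 50
        v = np.concatenate([np.full(s, 10.0), np.zeros(60)])
        out = smooth_running_average(make_trace(v), 27.0).values
        for j in range(27):
            assert out[s + j] == pytest.approx(10.0 * (26 - j) / 27.0)
        assert out[s + 27] == 0.0

    def test_first_sample_untouched(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        out = smooth_running_average(make_trace(v), 27.0)
        assert out.values[0] == v[0]

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window exceeds trace"):
            smooth_running_average(make_trace(np.ones(10)), 27.0)

    @given(hst.integers(min_value=1, max_value=60))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_direct_trailing_mean(self, window_ms):
        rng = np.random.default_rng(window_ms)
        v = rng.normal(size=80)
        out = smooth_running_average(make_trace(v), float(window_ms)).values
        n = max(1, round(window_ms))
        direct = [v[max(0, k - n + 1): k + 1].mean() for k in range(80)]
        np.testing.assert_allclose(out, direct, atol=1e-12)


class TestBaseline:
    def test_constant(self):
        tr = make_trace(np.full(1000, 100.0))
        assert baseline_level(tr, 800.0, 500.0) == 100.0

    def test_ramp_mean_is_midpoint(self):
        # 0 -> 100 mV linear over the 500 ms window preceding onset
        t = np.arange(600.0)
        v = np.clip((t - 100.0) / 500.0, 0, 1) * 100.0
        tr = make_trace(v)
        assert baseline_level(tr, 600.0, 500.0) == pytest.approx(50.0, abs=0.2)

    def test_onset_at_trace_start_rejected(self):
        tr = make_trace(np.ones(100))
        with pytest.raises(ValueError, match="baseline window not covered"):
            baseline_level(tr, 0.0, 500.0)

    def test_onset_sample_excluded(self):
        v = np.ones(100)
        v[50] = 1000.0  # the onset sample must not leak into the baseline
        assert baseline_level(make_trace(v), 50.0, 50.0) == 1.0


class TestReflectanceDetector:
    def test_flat_trace_censored_at_cutoff(self, default_cfg):
        stim = StimulusEvent("thermal", onset=500.0, cutoff=20000.0)
        tr = make_trace(np.full(20501, 100.0))
        res = detect_withdrawal_reflectance(tr, stim, default_cfg)
        assert not res.detected and res.censored
        assert res.latency == 20000.0 and res.censor_time == 20000.0

    def test_short_dip_rejected_by_persistence(self, default_cfg, pulse_stim):
        # the whole rule runs on the smoothed signal, so the relevant
        # duration is the smoothed sub-threshold run: a 12 ms raw dip of
        # 5 mV yields an 18 ms smoothed run below baseline-2 -> rejected
        v = np.full(2000, 100.0)
        v[600:612] -= 5.0
        res = detect_withdrawal_reflectance(make_trace(v), pulse_stim, default_cfg)
        assert not res.detected and res.censored

    def test_step_drop_latency_reflects_smoothing(self, default_cfg, pulse_stim):
        # noiseless 5 mV step at onset+100: smoothed deficit 5*(j+1)/27
        # first exceeds 2 mV at j=10 -> latency 110 ms
        v = np.full(2000, 100.0)
        v[600:] -= 5.0
        res = detect_withdrawal_reflectance(make_trace(v), pulse_stim, default_cfg)
        assert res.detected and res.latency == 110.0

    def test_wrong_units_rejected(self, default_cfg, pulse_stim):
        tr = make_trace(np.full(2000, 100.0), units="px")
        with pytest.raises(UnitError):
            detect_withdrawal_reflectance(tr, pulse_stim, default_cfg)

    def test_missing_baseline_rejected(self, default_cfg):
        stim = StimulusEvent("thermal", onset=100.0, cutoff=500.0)
        with pytest.raises(ValueError):
            detect_withdrawal_reflectance(make_trace(np.full(700, 1.0)), stim, default_cfg)

    @pytest.mark.parametrize("dur_ms", [1, 5, 10, 15, 19, 20])
    def test_excursions_up_to_persistence_never_reported(self, dur_ms, pulse_stim):
        # raw (unsmoothed) rule so excursion duration is exact
        cfg = DetectionConfig(smooth_window=1.0)
        v = np.full(2000, 100.0)
        v[700: 700 + dur_ms] -= 10.0
        res = detect_withdrawal_reflectance(make_trace(v), pulse_stim, cfg)
        assert not res.detected

    def test_excursion_just_past_persistence_reported(self, pulse_stim):
        cfg = DetectionConfig(smooth_window=1.0)
        v = np.full(2000, 100.0)
        v[700:721] -= 10.0  # 21 samples at 1 kHz -> 21 ms > 20 ms
        res = detect_withdrawal_reflectance(make_trace(v), pulse_stim, cfg)
        assert res.detected and res.latency == 200.0

    def test_matches_brute_force_oracle_on_noisy_traces(self, default_cfg, pulse_stim):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            v = 100.0 + rng.normal(0, 1.0, 2000)
            if seed % 2:
                k = 600 + 40 * (seed % 5)
                v[k:] -= 5.0
            tr = make_trace(v)
            res = detect_withdrawal_reflectance(tr, pulse_stim, default_cfg)
            det_o, lat_o = brute_force_reflectance(tr, pulse_stim, default_cfg)
            assert res.detected == det_o
            assert res.latency == pytest.approx(lat_o)


class TestHeightDetector:
    def test_step_rise_detected(self, default_cfg, pulse_stim):
        v = np.full(2000, 50.0)
        v[620:] += 10.0
        res = detect_withdrawal_height(make_trace(v, units="px"), pulse_stim, default_cfg)
        assert res.detected and res.latency == 120.0 and res.channel == "height"

    def test_subcriterion_rise_ignored(self, default_cfg, pulse_stim):
        v = np.full(2000, 50.0)
        v[620:] += 5.0  # below the 6 px criterion
        res = detect_withdrawal_height(make_trace(v, units="px"), pulse_stim, default_cfg)
        assert not res.detected and res.censored

    def test_downward_press_never_triggers(self, default_cfg, pulse_stim):
        v = np.full(2000, 50.0)
        v[620:] -= 20.0  # paw pressed down: rise criterion only
        res = detect_withdrawal_height(make_trace(v, units="px"), pulse_stim, default_cfg)
        assert not res.detected

    def test_wrong_units_rejected(self, default_cfg, pulse_stim):
        with pytest.raises(UnitError):
            detect_withdrawal_height(make_trace(np.full(2000, 50.0)), pulse_stim, default_cfg)


class TestForceDetector:
    @staticmethod
    def _ramp_trace(peak=40.0, rate=10.0, cutoff=6000.0, noise_sd=0.0, seed=0):
        from nocirig.rig_sim import simulate_force_trial

        return simulate_force_trial(peak, rate, noise_sd=noise_sd, cutoff=cutoff, seed=seed)

    def test_ramp_and_drop(self, default_cfg):
        trace, truth = self._ramp_trace()
        stim = StimulusEvent("mechanical", waveform="ramp", onset=0.0, cutoff=6000.0)
        res = detect_withdrawal_force(trace, stim, default_cfg)
        assert res.detected
        assert res.latency == pytest.approx(4000.0, abs=default_cfg.smooth_window + 5)
        assert res.threshold_force == pytest.approx(40.0, abs=1e-9)

    def test_monotone_ramp_censored(self, default_cfg):
        trace, _ = self._ramp_trace(peak=100.0, rate=10.0, cutoff=6000.0)  # never reached
        stim = StimulusEvent("mechanical", waveform="ramp", onset=0.0, cutoff=6000.0)
        res = detect_withdrawal_force(trace, stim, default_cfg)
        assert not res.detected and res.censored
        assert np.isnan(res.threshold_force)

    def test_noisy_ramp_detects_only_true_drop(self, default_cfg):
        for seed in range(5):
            trace, truth = self._ramp_trace(noise_sd=1.0, seed=seed)
            stim = StimulusEvent("mechanical", waveform="ramp", onset=0.0, cutoff=6000.0)
            res = detect_withdrawal_force(trace, stim, default_cfg)
            assert res.detected
            assert abs(res.latency - truth[0]) < 50.0
            assert res.threshold_force == pytest.approx(truth[1], abs=4.0)

    def test_all_zero_trace_censored(self, default_cfg):
        stim = StimulusEvent("mechanical", waveform="ramp", onset=0.0, cutoff=1000.0)
        trace = make_trace(np.zeros(1001), units="mN")
        res = detect_withdrawal_force(trace, stim, default_cfg)
        assert not res.detected and res.censored and np.isnan(res.threshold_force)


class TestStreamingDetector:
    def test_out_of_order_push_rejected(self, default_cfg, pulse_stim):
        det = StreamingWithdrawalDetector(pulse_stim, default_cfg)
        det.push(0.0, 1.0)
        det.push(1.0, 1.0)
        with pytest.raises(ValueError, match="out-of-order"):
            det.push(0.5, 1.0)

    def test_replay_equals_offline_on_random_traces(self, default_cfg, pulse_stim):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            v = 100.0 + rng.normal(0, 1.0, 2000)
            if seed % 3 != 0:
                v[550 + 10 * (seed % 30):] -= 5.0
            tr = make_trace(v)
            off = detect_withdrawal_reflectance(tr, pulse_stim, default_cfg)
            stream = StreamingWithdrawalDetector(pulse_stim, default_cfg).replay(tr)
            assert (off.detected, off.censored) == (stream.detected, stream.censored)
            assert off.latency == pytest.approx(stream.latency)

    def test_emission_lags_crossing_by_persistence(self, default_cfg, pulse_stim):
        # latency reports the crossing sample; the event fires only once the
        # sub-threshold run has lasted just past the persistence period
        v = np.full(2000, 100.0)
        v[600:] -= 10.0
        tr = make_trace(v)
        det = StreamingWithdrawalDetector(pulse_stim, default_cfg)
        emitted_at = None
        for t, val in zip(tr.times, tr.values):
            if det.push(float(t), float(val)) is not None:
                emitted_at = t
                break
        res = det.result
        assert res.detected
        run_samples = int(np.floor(default_cfg.persistence / tr.dt)) + 1
        assert emitted_at - (pulse_stim.onset + res.latency) == pytest.approx(
            (run_samples - 1) * tr.dt
        )

    def test_stream_ending_at_cutoff_finalizes_censored(self, default_cfg, pulse_stim):
        v = np.full(2000, 100.0)
        res = StreamingWithdrawalDetector(pulse_stim, default_cfg).replay(make_trace(v))
        assert res.censored and res.latency == pulse_stim.cutoff


class TestCensoringConservation:
    def test_detected_plus_censored_equals_trials(self, default_cfg, pulse_stim):
        n_det = n_cen = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            v = 100.0 + rng.normal(0, 0.5, 2000)
            if seed % 2:
                v[700:] -= 5.0
            res = detect_withdrawal_reflectance(make_trace(v), pulse_stim, default_cfg)
            n_det += res.detected
            n_cen += res.censored
        assert n_det + n_cen == 40
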