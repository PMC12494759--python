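"""Upsampled triggered averages, IPSP features, spike probability, CV maps."""

import numpy as np
import pytest

from voltdend.traces import SpikeTrain, compute_baseline
from voltdend.triggered import (
    ipsp_features,
    segment_response_map,
    spike_probability,
    spike_triggered_average,
    upsampled_sta,
)

FR = 440.0


class TestUpsampledSta:
    def test_frame_aligned_triggers_reproduce_plain_average(self):
        rng = np.random.default_rng(0)
        ft = np.arange(int(30 * FR)) / FR
        trace = rng.normal(0, 1, len(ft))
        k = np.arange(10, 12000, 600)
        triggers = ft[k]  # exactly on frame starts
        sta = upsampled_sta(trace, ft, triggers, window_ms=(0, 50), target_rate_hz=FR)
        plain = np.mean([trace[i : i + len(sta.time_ms)] for i in k], axis=0)
        assert np.allclose(sta.mean, plain)
        assert not sta.interpolated.any()

    def test_single_trigger_mean_is_the_trial(self):
        ft = np.arange(int(5 * FR)) / FR
        trace = np.sin(ft)
        sta = upsampled_sta(trace, ft, np.array([2.0]), window_ms=(0, 50), target_rate_hz=FR)
        assert sta.n == 1
        assert np.all(sta.sd[~sta.interpolated] == 0)

    def test_sinusoid_reconstruction_rmse(self):
        f = 30.0
        ft = np.arange(int(120 * FR)) / FR
        trace = np.sin(2 * np.pi * f * ft)
        rng = np.random.default_rng(0)
        k = np.sort(rng.choice(np.arange(40, int(119 * f) - 40), 200, replace=False))
        triggers = np.round(k / f * 20000) / 20000  # DAQ-grid trigger times
        sta = upsampled_sta(trace, ft, triggers, window_ms=(0, 100), target_rate_hz=2000.0)
        expected = np.sin(2 * np.pi * f * sta.time_ms / 1000)
        rmse = np.sqrt(np.mean((sta.mean - expected) ** 2))
        assert rmse <= 0.02  # 2% of unit amplitude

    def test_out_of_range_triggers_dropped_with_warning(self):
        ft = np.arange(int(5 * FR)) / FR
        with pytest.warns(UserWarning, match="dropped"):
            sta = upsampled_sta(np.ones(len(ft)), ft, np.array([0.01, 2.0]),
                                window_ms=(-100, 100))
        assert sta.n == 1 and sta.dropped == [0]
        with pytest.raises(ValueError, match="all triggers dropped"):
            upsampled_sta(np.ones(len(ft)), ft, np.array([0.01]), window_ms=(-100, 100))


class TestSpikeTriggeredAverage:
    def _template_trace(self, phases, sd_ms=4.0, amp=0.3, duration=60.0, spacing=1.5):
        ft = np.arange(int(duration * FR)) / FR
        trace = np.zeros(len(ft))
        centers = np.arange(2.0, duration - 2.0, spacing)[: len(phases)] + phases
        for c in centers:
            trace += amp * np.exp(-0.5 * ((ft - c) / (sd_ms / 1000)) ** 2)
        return ft, trace, centers

    def test_random_subframe_phases_recover_template(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 1 / FR, 150)
        ft, trace, centers = self._template_trace(phases, duration=120.0, spacing=0.75)
        from voltdend.traces import detect_spikes

        spikes = detect_spikes(trace + rng.normal(0, 1e-4, len(ft)), FR)
        keep = np.array([np.min(np.abs(centers - t)) < 0.005 for t in spikes.times])
        assert keep.sum() == len(centers)  # every template event found
        matched = SpikeTrain(
            times=spikes.times[keep], indices=spikes.indices[keep],
            amplitudes=spikes.amplitudes[keep], baselines=spikes.baselines[keep],
            offsets_ms=spikes.offsets_ms[keep], widths_ms=spikes.widths_ms[keep],
            confident=spikes.confident[keep],
        )
        sta = spike_triggered_average(trace, ft, matched, window_ms=(-20, 20),
                                      target_rate_hz=2000.0)
        expected = 0.3 * np.exp(-0.5 * (sta.time_ms / 4.0) ** 2)
        assert np.max(np.abs(sta.mean - expected)) <= 0.01 * 0.3  # within 1%

    def test_frame_aligned_spikes_give_zero_offsets(self):
        ft, trace, centers = self._template_trace(np.zeros(30))
        from voltdend.traces import detect_spikes

        spikes = detect_spikes(trace + np.random.default_rng(2).normal(0, 1e-4, len(ft)), FR)
        assert np.median(np.abs(spikes.offsets_ms)) < 0.3

    def test_three_spikes_runs_with_n_recorded(self):
        ft, trace, centers = self._template_trace(np.zeros(3))
        spikes = SpikeTrain(
            times=centers, indices=(centers * FR).astype(int),
            amplitudes=np.full(3, 0.3), baselines=np.zeros(3),
            offsets_ms=np.zeros(3), widths_ms=np.full(3, 4.0),
            confident=np.ones(3, bool),
        )
        sta = spike_triggered_average(trace, ft, spikes, window_ms=(-20, 20))
        assert sta.n == 3


class TestIpspFeatures:
    def _dip_baseline(self, depth=0.05, t_peak_s=0.08, trigger=2.0, duration=6.0):
        ft = np.arange(int(duration * FR)) / FR
        base = np.zeros(len(ft))
        # alpha-like dip with minimum at trigger + t_peak_s
        tau_r, tau_d = 0.02, 0.12
        t = ft - trigger
        k = np.where(t > 0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0)
        t_pk = np.log(tau_d / tau_r) / (1 / tau_r - 1 / tau_d)
        k /= np.exp(-t_pk / tau_d) - np.exp(-t_pk / tau_r)
        return ft, -depth * k

    def test_constructed_dip_amplitude_and_latency(self):
        ft, base = self._dip_baseline()
        f = ipsp_features(base, ft, trigger=2.0)
        assert f.amplitude == pytest.approx(0.05, rel=1e-3)
        t_pk = np.log(0.12 / 0.02) / (1 / 0.02 - 1 / 0.12)
        assert f.time_to_peak_ms == pytest.approx(t_pk * 1000, abs=3.0)
        assert 0 < f.latency10_ms < f.time_to_peak_ms

    def test_flat_trace_flagged(self):
        ft = np.arange(int(4 * FR)) / FR
        f = ipsp_features(np.zeros(len(ft)), ft, trigger=2.0)
        assert f.flagged and not np.isfinite(f.latency10_ms)

    def test_fully_gated_window_flagged(self):
        ft, base = self._dip_baseline()
        missing = (ft > 2.0) & (ft < 2.3)
        f = ipsp_features(base, ft, trigger=2.0, missing=missing)
        assert f.flagged

    def test_amplitude_invariant_to_baseline_offset(self):
        ft, base = self._dip_baseline()
        f0 = ipsp_features(base, ft, trigger=2.0)
        f1 = ipsp_features(base + 0.37, ft, trigger=2.0)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-12)

    def test_graded_led_levels_increase_amplitude(self):
        from voltdend.config import PipelineConfig
        from voltdend.pipeline import analyze_fov
        from voltdend.synth import SceneConfig, simulate_movie

        cfg = SceneConfig(
            n_cells=1, field_shape=(14, 48), duration_s=38.0, led_enabled=True,
            led_levels=[0.5, 1.0, 1.5], seed=7,
        )
        movie, daq, gt = simulate_movie(cfg)
        res = analyze_fov(movie, daq, gt.cell_weights, PipelineConfig())[0]
        levels = daq.led_levels
        means = [np.nanmean(res.ipsp_trials[levels == lv]) for lv in (0.5, 1.0, 1.5)]
        assert means[0] < means[1] < means[2]


class TestSpikeProbability:
    def test_every_trigger_followed_by_spike(self):
        trig = np.arange(1.0, 10.0, 1.0)
        spikes = trig + 0.05
        assert spike_probability(spikes, trig, 0.15) == 1.0

    def test_no_spikes(self):
        assert spike_probability(np.array([]), np.arange(1.0, 5.0), 0.15) == 0.0

    def test_poisson_closed_form(self):
        r, w = 4.0, 0.15
        probs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            spikes = np.sort(rng.uniform(0, 70, rng.poisson(r * 70)))
            trig = np.arange(1.0, 61.0, 1.0)
            probs.append(spike_probability(spikes, trig, w))
        expected = 1 - np.exp(-r * w)
        se = np.std(probs) / np.sqrt(50)
        assert abs(np.mean(probs) - expected) <= 3 * se

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            spike_probability(np.array([1.0]), np.array([1.0, 1.05]), 0.15)


class TestSegmentResponseMap:
    def _seg_baselines(self, depths, trigger=2.0, duration=6.0):
        ft = np.arange(int(duration * FR)) / FR
        t = ft - trigger
        k = np.where(t > 0, np.exp(-t / 0.12) - np.exp(-t / 0.02), 0.0)
        k /= k.max()
        return ft, np.stack([-d * k for d in depths])

    def test_identical_segments_cv_zero(self):
        ft, base = self._seg_baselines([0.05, 0.05, 0.05])
        m = segment_response_map(base, ft, triggers=np.array([2.0]))
        assert m.cv == pytest.approx(0.0, abs=1e-9)

    def test_cv_formula(self):
        vals = np.array([1.5, 2.5])  # sd=x, mean=2 -> cv = sd/2
        ft, base = self._seg_baselines(vals * 0.02)
        m = segment_response_map(base, ft, triggers=np.array([2.0]))
        expected = np.std(vals * 0.02, ddof=1) / np.mean(vals * 0.02)
        assert m.cv == pytest.approx(expected, rel=1e-3)

    def test_cv_invariant_to_positive_rescaling(self):
        ft, base = self._seg_baselines([0.03, 0.05, 0.08])
        m1 = segment_response_map(base, ft, triggers=np.array([2.0]))
        m2 = segment_response_map(3.7 * base, ft, triggers=np.array([2.0]))
        assert m2.cv == pytest.approx(m1.cv, rel=1e-9)

    def test_cs_amplitude_uses_common_event_set(self):
        rng = np.random.default_rng(0)
        seg_dff = rng.normal(0, 0.01, (3, 4000))
        idx = np.array([500, 1500, 2500])
        for s, gain in enumerate([1.0, 2.0, 3.0]):
            seg_dff[s, idx] += 0.3 * gain
        spikes = SpikeTrain(
            times=idx / FR, indices=idx, amplitudes=np.full(3, 0.3),
            baselines=np.zeros(3), offsets_ms=np.zeros(3),
            widths_ms=np.full(3, 3.0), confident=np.ones(3, bool),
        )
        m = segment_response_map(
            np.zeros_like(seg_dff), np.arange(4000) / FR, spikes=spikes,
            feature="cs_amplitude", segment_dff=seg_dff,
        )
        assert m.per_segment[0] < m.per_segment[1] < m.per_segment[2]

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="2 segments"):
            segment_response_map(np.zeros((1, 100)), np.arange(100) / FR,
                                 triggers=np.array([0.1]))
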