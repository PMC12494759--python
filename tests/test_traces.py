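"""-dF/F0 normalization, gating repair, baseline filter, spike detection, d'."""

import numpy as np
import pytest

from voltdend.synth import _diff_exp, cs_kernel_taus
from voltdend.traces import (
    SpikeTrain,
    baseline_amplitude_regression,
    blank_gating,
    compute_baseline,
    compute_dff,
    detect_spikes,
    discriminability,
)

FR = 440.0


def cs_trace(spike_times, amp, noise_sd, duration=60.0, seed=0):
    """Noise + complex-spike kernels, peak-aligned to the requested times."""
    rng = np.random.default_rng(seed)
    n = int(duration * FR)
    tr, td = cs_kernel_taus(1.0, 10.5)
    t_pk = np.log(td / tr) / (1 / tr - 1 / td) / 1000
    t = np.arange(n) / FR
    x = rng.normal(0, noise_sd, n)
    for t0 in spike_times:
        x += amp * _diff_exp((t - t0 + t_pk) * 1000, tr, td)
    return x


class TestDff:
    def test_constant_trace_is_zero(self):
        assert np.allclose(compute_dff(np.full(2000, 5.0), FR), 0.0)

    def test_dip_flips_sign(self):
        x = np.ones(4400)
        x[2200] = 0.9
        d = compute_dff(x, FR)
        assert d[2200] == pytest.approx(0.10, abs=5e-3)  # positive = depolarization

    def test_matches_brute_force_windowed_oracle(self):
        rng = np.random.default_rng(0)
        x = 100 * np.exp(-np.arange(2200) / FR * 0.01) + rng.normal(0, 0.1, 2200)
        d = compute_dff(x, FR)
        k = int(round(2.0 * FR))
        brute = np.empty_like(x)
        for i in range(len(x)):
            w = x[max(0, i - k // 2) : min(len(x), i + (k - 1) // 2 + 1)]
            brute[i] = -(x[i] - w.mean()) / w.mean()
        assert np.allclose(d, brute, atol=1e-12)
        assert np.abs(d).max() <= 0.012  # slow 1%/s bleach barely registers

    def test_commutes_with_positive_scaling(self):
        rng = np.random.default_rng(1)
        x = 10 + rng.normal(0, 0.5, 3000)
        assert np.allclose(compute_dff(x, FR), compute_dff(7.3 * x, FR), atol=1e-12)

    def test_nonpositive_f0_rejected(self):
        x = np.concatenate([np.ones(1000), -np.ones(1000)])
        with pytest.raises(ValueError, match="F0"):
            compute_dff(x, FR)

    def test_trailing_window_option(self):
        x = np.arange(1.0, 2001.0)
        d = compute_dff(x, FR, centered=False)
        # trailing mean <= x for an increasing trace -> -dF/F0 <= 0
        assert np.all(d[10:] <= 0)


class TestBlankGating:
    def test_linear_interpolation(self):
        x = np.array([1.0, 9, 9, 9, 2.0])
        m = np.array([False, True, True, True, False])
        assert np.allclose(blank_gating(x, m), [1.0, 1.25, 1.5, 1.75, 2.0])

    def test_no_gating_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(blank_gating(x, np.zeros(10, bool)), x)

    def test_leading_gap_nearest_valid(self):
        x = np.array([9.0, 9.0, 0.7, 1.0])
        m = np.array([True, True, False, False])
        assert np.allclose(blank_gating(x, m), [0.7, 0.7, 0.7, 1.0])

    def test_fully_gated_rejected(self):
        with pytest.raises(ValueError, match="entire"):
            blank_gating(np.ones(5), np.ones(5, bool))


class TestBaseline:
    def test_dc_passes_unchanged(self):
        x = np.full(4000, 3.3)
        assert np.allclose(compute_baseline(x, FR, 4.0), x)

    def test_50hz_attenuated_40db(self):
        t = np.arange(0, 10, 1 / FR)
        x = np.sin(2 * np.pi * 50 * t)
        y = compute_baseline(x, FR, 4.0)
        assert np.abs(y[500:-500]).max() < 10 ** (-40 / 20)

    def test_matches_analytic_squared_butterworth_response(self):
        # zero-phase (forward-backward) filtering squares the magnitude
        from scipy.signal import butter, sosfreqz

        t = np.arange(0, 20, 1 / FR)
        x = np.sin(2 * np.pi * 10 * t)
        y = compute_baseline(x, FR, 4.0)
        _, h = sosfreqz(butter(5, 4.0, fs=FR, output="sos"), worN=[10.0], fs=FR)
        assert np.abs(y[2000:-2000]).max() == pytest.approx(np.abs(h[0]) ** 2, rel=1e-3)

    def test_05hz_preserved(self):
        t = np.arange(0, 20, 1 / FR)
        x = np.sin(2 * np.pi * 0.5 * t) + np.sin(2 * np.pi * 50 * t)
        y = compute_baseline(x, FR, 4.0)
        target = np.sin(2 * np.pi * 0.5 * t)
        amp = np.ptp(y[2000:-2000]) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_zero_phase(self):
        t = np.arange(0, 20, 1 / FR)
        x = np.sin(2 * np.pi * 0.5 * t)
        y = compute_baseline(x, FR, 4.0)
        lag = np.argmax(np.correlate(y[2000:6000], x[2000:6000], "full")) - 3999
        assert abs(lag) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_baseline(np.ones(100), FR, 300.0)


class TestDetect:
    def test_three_template_spikes_recovered(self):
        truth = [10.0, 25.0, 40.0]
        x = cs_trace(truth, amp=0.10, noise_sd=0.01, seed=1)
        spikes = detect_spikes(x, FR)
        assert len(spikes) == 3
        for t0 in truth:
            assert np.min(np.abs(spikes.times - t0)) <= 1.01 / FR  # within one frame

    def test_two_spikes_15ms_apart_both_found(self):
        x = cs_trace([10.0, 10.015], amp=0.12, noise_sd=0.01, seed=2)
        spikes = detect_spikes(x, FR)
        assert len(spikes) == 2
        assert np.diff(spikes.times)[0] >= 1.0 / FR

    def test_noise_only_false_positives_match_monte_carlo_oracle(self):
        # oracle: independent brute-force recount of smoothed-residual maxima
        # above 3 robust sigma with the same collapse rule
        from scipy.ndimage import gaussian_filter1d

        n_detected, n_oracle = [], []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 0.01, int(60 * FR))
            spikes = detect_spikes(x, FR)
            n_detected.append(len(spikes))
            base = compute_baseline(x, FR, 4.0)
            resid = gaussian_filter1d(x, 1.0) - base
            sigma = 1.4826 * np.median(np.abs((x - base) - np.median(x - base)))
            above = resid > 3 * sigma
            # count well-separated threshold excursions
            runs = np.diff(np.flatnonzero(np.diff(above.astype(int)) == 1))
            n_oracle.append(int(above.any()) + int((runs > 11).sum()) if above.any() else 0)
        se = max(np.std(n_oracle) / np.sqrt(20), 0.05)
        assert abs(np.mean(n_detected) - np.mean(n_oracle)) <= 3 * se + 0.5

    def test_second_pass_sigma_not_larger(self):
        truth = np.arange(2.0, 58.0, 0.8)
        x = cs_trace(truth, amp=0.3, noise_sd=0.02, seed=3)
        spikes = detect_spikes(x, FR)
        assert spikes.sigma_pass2 <= spikes.sigma_pass1

    def test_amplitude_recovery_unbiased_at_high_dprime(self):
        truth = np.arange(2.0, 58.0, 1.5)
        x = cs_trace(truth, amp=0.3, noise_sd=0.02, seed=4)
        spikes = detect_spikes(x, FR)
        clean = cs_trace(truth, amp=0.3, noise_sd=0.0)
        rel_err = []
        for t0, a in zip(spikes.times, spikes.amplitudes):
            i = int(round(t0 * FR))
            rel_err.append(abs(a - clean[i]) / clean[i])
        assert np.median(rel_err) <= 0.05

    def test_offsets_within_half_frame(self):
        truth = np.arange(2.0, 58.0, 1.5) + 0.0007  # sub-frame phase
        x = cs_trace(truth, amp=0.3, noise_sd=0.01, seed=5)
        spikes = detect_spikes(x, FR)
        assert np.all(np.abs(spikes.offsets_ms) <= 1000 / FR / 2 + 1e-9)

    def test_flat_trace_sigma_zero_raises(self):
        with pytest.raises(ValueError, match="noise"):
            detect_spikes(np.zeros(4000), FR)


class TestDiscriminability:
    @staticmethod
    def _train(times, amps, baselines=None):
        n = len(times)
        return SpikeTrain(
            times=np.asarray(times, float),
            indices=(np.asarray(times) * FR).astype(int),
            amplitudes=np.asarray(amps, float),
            baselines=np.zeros(n) if baselines is None else np.asarray(baselines, float),
            offsets_ms=np.zeros(n),
            widths_ms=np.full(n, 3.0),
            confident=np.ones(n, bool),
        )

    def test_formula(self):
        rng = np.random.default_rng(0)
        dff = rng.normal(0, 1.0, int(60 * FR))
        spikes = self._train(np.arange(2.0, 58.0, 1.0), np.full(56, 5.0))
        d = discriminability(dff, spikes, FR, seed=0)
        assert d.d_prime == pytest.approx((5.0 - d.mu_b) / d.sigma_b)
        assert d.d_prime == pytest.approx(5.0, abs=1.5)

    def test_zero_when_amplitudes_match_background(self):
        rng = np.random.default_rng(1)
        dff = rng.normal(0.2, 0.5, int(20 * FR))
        spikes = self._train(np.arange(2.0, 18.0, 2.0), np.full(8, 0.2))
        d = discriminability(dff, spikes, FR, seed=1)
        assert abs(d.d_prime) < 1.5

    def test_simulator_dprime_matches_snr_oracle(self):
        from voltdend.synth import SceneConfig, calibrate_noise_for_dprime, simulate_movie
        from voltdend.traces import DffTrace

        errs = []
        base = SceneConfig(n_cells=1, field_shape=(16, 48), duration_s=60.0)
        noise = calibrate_noise_for_dprime(base, 6.0)
        for seed in range(6):
            cfg = base.model_copy(update={"noise_scale": noise, "seed": seed})
            movie, daq, gt = simulate_movie(cfg)
            w = gt.cell_weights[0].ravel()
            raw = movie.data.reshape(movie.n_frames, -1) @ (w / w.sum())
            d = DffTrace.from_raw(raw, cfg.frame_rate)
            spikes = d.detect()
            got = discriminability(d.values, spikes, cfg.frame_rate, seed=seed)
            # forward-model oracle: true frame-grid amplitude over measured
            # background sd
            idx = np.clip((gt.spike_times[0] * cfg.frame_rate).round().astype(int), 0, None)
            true_amp = gt.voltage[0][idx].mean()
            oracle = true_amp / got.sigma_b
            errs.append(abs(got.d_prime - oracle) / oracle)
        assert np.median(errs) < 0.15

    def test_too_few_spikes(self):
        dff = np.zeros(int(20 * FR))
        spikes = self._train([2.0, 4.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="5 spikes"):
            discriminability(dff, spikes, FR)


class TestBaselineAmplitudeRegression:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-0.05, 0.05, 40)
        spikes = TestDiscriminability._train(
            np.linspace(1, 50, 40), 2 + 0.8 * base, baselines=base
        )
        slope, intercept, p = baseline_amplitude_regression(spikes)
        assert slope == pytest.approx(0.8)
        assert intercept == pytest.approx(2.0)
        assert p < 1e-6

    def test_null_pvalues_uniform(self):
        from scipy.stats import kstest

        pvals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, 0.02, 30)
            amp = rng.normal(0.3, 0.05, 30)  # independent of baseline
            spikes = TestDiscriminability._train(np.linspace(1, 40, 30), amp, base)
            pvals.append(baseline_amplitude_regression(spikes)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_two_spikes_rejected(self):
        spikes = TestDiscriminability._train([1.0, 2.0], [1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="3"):
            baseline_amplitude_regression(spikes)

    def test_constant_baseline_rejected(self):
        spikes = TestDiscriminability._train([1.0, 2.0, 3.0], [1.0, 2.0, 1.5], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="constant"):
            baseline_amplitude_regression(spikes)
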