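"""Reproducible validation benchmarks: every stage of the pipeline is run
against seeded synthetic data with known ground truth, and the recovery
quality is summarized as plain numbers.

Each function re-generates its inputs from scratch (nothing is cached or
looked up), runs the package's own analysis path, and measures the result
against the generator's ground truth or an analytic oracle.  These are the
quantities a user should inspect before trusting the pipeline on real
recordings; ``scripts/acceptance.py`` writes them to JSON.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import kstest

from .config import PipelineConfig
from .pipeline import (
    analyze_fov,
    simulate_log_ratio_features,
    simulate_plasticity_experiment,
)
from .plasticity import group_difference
from .segmentation import (
    arc_segment_edges,
    cluster_segments,
    extract_traces,
    fit_dendrite_path,
    refine_mask,
    segment_path,
)
from .synchrony import ccg_significance, crosscorrelogram, synchrony_width
from .synth import (
    SceneConfig,
    calibrate_noise_for_dprime,
    simulate_movie,
    simulate_spike_trains,
)
from .traces import DffTrace, discriminability
from .triggered import ipsp_features, segment_response_map, upsampled_sta

__all__ = [
    "detection_benchmark",
    "kinetics_benchmark",
    "photobleach_benchmark",
    "fv_benchmark",
    "clustering_benchmark",
    "sta_benchmark",
    "ccg_null_benchmark",
    "ccg_jitter_benchmark",
    "ipsp_benchmark",
    "cv_benchmark",
    "plasticity_benchmark",
    "plasticity_null_benchmark",
    "shuffle_uniformity_benchmark",
]


def _sub_seed(seed: int, tag: int, k: int = 0) -> int:
    return int(np.random.SeedSequence([int(seed), tag, k]).generate_state(1)[0] % (2**31))


def _whole_cell_trace(movie, gt, cell: int = 0) -> np.ndarray:
    w = gt.cell_weights[cell].ravel()
    return movie.data.reshape(movie.n_frames, -1) @ (w / w.sum())


# --------------------------------------------------------------------------


def detection_benchmark(
    seed: int = 0,
    n_seeds: int = 20,
    target_dprime: float = 5.0,
    duration_s: float = 60.0,
) -> dict:
    """Complex-spike detection on movies calibrated to d' ~ 5.

    Sensitivity, false positives per minute, spike-time error (frames) and
    the measured d', all medians over seeds.  A detection within 3.5 frames
    of a true spike counts as a hit (timing accuracy is reported
    separately); anything else is a false positive.
    """
    base = SceneConfig(n_cells=1, field_shape=(16, 64), duration_s=duration_s)
    noise = calibrate_noise_for_dprime(base, target_dprime)
    tol = 3.5 / base.frame_rate
    sens, fps, terr, dps = [], [], [], []
    for k in range(n_seeds):
        cfg = base.model_copy(update={"noise_scale": noise, "seed": _sub_seed(seed, 1, k)})
        movie, daq, gt = simulate_movie(cfg)
        dfft = DffTrace.from_raw(_whole_cell_trace(movie, gt), cfg.frame_rate)
        spikes = dfft.detect()
        truth = gt.spike_times[0]
        if len(truth) == 0 or len(spikes) == 0:
            continue
        hits = np.array([np.min(np.abs(spikes.times - t)) <= tol for t in truth])
        sens.append(hits.mean())
        fps.append(sum(np.min(np.abs(truth - t)) > tol for t in spikes.times) / (duration_s / 60))
        errs = [
            np.min(np.abs(spikes.times - t)) * cfg.frame_rate
            for t in truth
            if np.min(np.abs(spikes.times - t)) <= tol
        ]
        terr.append(np.median(errs))
        dps.append(discriminability(dfft.values, spikes, cfg.frame_rate, seed=k).d_prime)
    return {
        "sensitivity_pct": float(np.median(sens) * 100),
        "false_positives_per_min": float(np.median(fps)),
        "spike_time_error_frames": float(np.median(terr)),
        "measured_dprime": float(np.median(dps)),
        "n": n_seeds,
    }


def kinetics_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Onset-exponential recovery: noiseless single fit, dual fit at SNR 100."""
    from .kinetics import fit_onset_exponential

    t = np.linspace(0.0, 1.0, 20001)
    lam, t0 = -50.0, 0.1
    y = 1.0 + 0.3 * np.where(t > t0, np.exp((t - t0) * lam), 1.0)
    f = fit_onset_exponential(y, t, "single")
    single_err = abs(f.lam - lam) / abs(lam) * 100
    t0_err = abs(f.t0 - t0) / (t[1] - t[0])
    lam1, lam2 = -150.0, -8.0
    errs = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 2, k))
        y = 1.0 + np.where(
            t > t0, 0.2 * np.exp((t - t0) * lam1) + 0.1 * np.exp((t - t0) * lam2), 0.3
        )
        fit = fit_onset_exponential(y + rng.normal(0, 0.3 / 100, len(t)), t, "dual")
        errs.append(max(abs(fit.lam - lam1) / abs(lam1), abs(fit.lam2 - lam2) / abs(lam2)))
    return {
        "single_lambda_error_pct": float(single_err),
        "single_t0_error_samples": float(t0_err),
        "dual_rate_error_pct": float(np.median(errs) * 100),
        "n": n_seeds,
    }


def photobleach_benchmark(seed: int = 0) -> dict:
    """Triple-exponential correction flatness and event-amplitude fidelity."""
    from .kinetics import correct_photobleach

    t = np.linspace(0.0, 10.0, 5000)
    y = 0.5 * np.exp(-t / 50) + 0.3 * np.exp(-t / 3) + 0.2 * np.exp(-t / 0.5)
    corr, _, _ = correct_photobleach(y, t)
    flatness = np.abs(corr - 1).max() * 100
    events = np.zeros_like(t)
    events[(t > 4) & (t < 4.3)] = 0.08
    events[(t > 7) & (t < 7.3)] = 0.15
    corr2, _, _ = correct_photobleach(y * (1 + events), t, baseline_mask=events == 0)
    errs = []
    for lo, hi, amp in ((4, 4.3, 0.08), (7, 7.3, 0.15)):
        got = corr2[(t > lo) & (t < hi)].mean() - 1.0
        errs.append(abs(got - amp) / amp * 100)
    return {"flatness_pct": float(flatness), "event_amplitude_error_pct": float(max(errs))}


def fv_benchmark() -> dict:
    """Exact linear F-V data must regress exactly."""
    from .kinetics import compute_fv_curve

    v = np.arange(-80.0, -45.0, 5.0)
    fv = compute_fv_curve(np.stack([v, 1.5 * (v + 70)], 1), (-80, -50))
    return {
        "slope_error_pct": float(abs(fv.slope_pct_per_mv - 1.5) / 1.5 * 100),
        "r_squared": float(fv.r_squared),
    }


def clustering_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Two-cell movies: fraction of seeds clustered into exactly the two
    ground-truth cells, plus the 24 um -> 5 segment arithmetic."""
    correct = 0
    for k in range(n_seeds):
        cfg = SceneConfig(
            n_cells=2, field_shape=(20, 64), duration_s=60.0, seed=_sub_seed(seed, 3, k)
        )
        movie, daq, gt = simulate_movie(cfg)
        traces, owner = [], []
        for ci, mask in enumerate(gt.cell_weights):
            refined = refine_mask(mask, 1.0)
            segset = segment_path(fit_dendrite_path(refined, cfg.pixel_size_um), refined)
            traces.append(extract_traces(movie, segset))
            owner.extend([ci] * segset.n_segments)
        clusters, _ = cluster_segments(np.vstack(traces), cfg.frame_rate)
        owner = np.asarray(owner)
        ok = len(clusters) == 2 and all(
            len(set(owner[c.segment_ids])) == 1 for c in clusters
        ) and {tuple(sorted(set(owner[c.segment_ids])))[0] for c in clusters} == {0, 1}
        correct += bool(ok)
    return {
        "cell_assignment_accuracy_pct": float(correct / n_seeds * 100),
        "segments_in_24um": int(len(arc_segment_edges(24.0, 4.8)) - 1),
        "n": n_seeds,
    }


def sta_benchmark(seed: int = 0) -> dict:
    """30 Hz sinusoid at 440 Hz, 200 asynchronous triggers, 2 kHz grid."""
    fr, f = 440.0, 30.0
    ft = np.arange(int(120 * fr)) / fr
    trace = np.sin(2 * np.pi * f * ft)
    rng = np.random.default_rng(_sub_seed(seed, 4))
    k = np.sort(rng.choice(np.arange(40, int(119 * f) - 40), 200, replace=False))
    triggers = np.round(k / f * 20000) / 20000
    sta = upsampled_sta(trace, ft, triggers, window_ms=(0, 100), target_rate_hz=2000.0)
    expected = np.sin(2 * np.pi * f * sta.time_ms / 1000)
    return {
        "rmse_pct_of_amplitude": float(np.sqrt(np.mean((sta.mean - expected) ** 2)) * 100),
        "n": int(sta.n),
    }


def ccg_null_benchmark(seed: int = 0, n_runs: int = 100, alpha: float = 0.01) -> dict:
    """Independent Poisson trains: fraction of runs with no significant bin."""
    rng = np.random.default_rng(_sub_seed(seed, 5))
    clean = 0
    for _ in range(n_runs):
        a = np.sort(rng.uniform(0, 600, rng.poisson(780)))
        b = np.sort(rng.uniform(0, 600, rng.poisson(780)))
        ccg = ccg_significance(crosscorrelogram(a, b), alpha=alpha)
        clean += not ccg.significant.any()
    return {"clean_null_runs_pct": float(clean / n_runs * 100), "n": n_runs}


def ccg_jitter_benchmark(seed: int = 0, n_seeds: int = 30) -> dict:
    """Fitted CCG Gaussian SD across microzone jitter {1, 2, 4, 8} ms."""
    medians = []
    for jit in (1.0, 2.0, 4.0, 8.0):
        sds = []
        for k in range(n_seeds):
            cfg = SceneConfig(
                n_cells=2, duration_s=600.0, microzone_parent=[0, 0],
                microzone_jitter_ms=jit, seed=_sub_seed(seed, 6, int(jit * 100) + k),
            )
            trains, _ = simulate_spike_trains(cfg)
            ccg = ccg_significance(crosscorrelogram(trains[0], trains[1]))
            res = synchrony_width(ccg)
            if np.isfinite(res.gauss_sd_ms):
                sds.append(res.gauss_sd_ms)
        medians.append(float(np.median(sds)))
    monotone = all(a < b for a, b in zip(medians, medians[1:]))
    return {
        "gauss_sd_ms_by_jitter": medians,
        "monotone_fraction": float(monotone),
        "sd_error_pct_at_2ms": float(abs(medians[1] - 2 * np.sqrt(2)) / (2 * np.sqrt(2)) * 100),
        "n": n_seeds,
    }


def _sta_amplitude(dfft: DffTrace, triggers: np.ndarray, frame_rate: float) -> float:
    sta = upsampled_sta(
        dfft.baseline, dfft.time_s, triggers, window_ms=(-280, 400), target_rate_hz=frame_rate
    )
    f = ipsp_features(sta.mean, sta.time_ms / 1000, 0.0)
    return f.amplitude


def ipsp_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Graded three-level LED stimulation: monotonicity and amplitude bias.

    Amplitudes are read from the per-level trigger-averaged baseline signal
    (60 stimuli at 0.5 Hz, i.e. 20 trials per level), compared with the
    programmed per-level -dF/F0 amplitude (ground-truth trial factors and
    heterogeneity gain included).
    """
    monotone = 0
    biases = []
    for k in range(n_seeds):
        cfg = SceneConfig(
            n_cells=1, field_shape=(14, 48), duration_s=122.0, led_enabled=True,
            led_levels=[0.5, 1.0, 1.5], seed=_sub_seed(seed, 7, k),
        )
        movie, daq, gt = simulate_movie(cfg)
        dfft = DffTrace.from_raw(
            _whole_cell_trace(movie, gt), cfg.frame_rate, gating_intervals=daq.gating
        )
        levels = daq.led_levels
        amps, truths = [], []
        for lv in (0.5, 1.0, 1.5):
            sel = levels == lv
            amps.append(_sta_amplitude(dfft, daq.led_onsets[sel], cfg.frame_rate))
            truths.append(
                cfg.ipsp_amplitude * lv * gt.trial_factors[sel].mean() * gt.ipsp_gain[0]
            )
        monotone += amps[0] < amps[1] < amps[2]
        biases.append((np.array(amps) / np.array(truths) - 1.0) * 100)
    return {
        "monotone_runs_pct": float(monotone / n_seeds * 100),
        "amplitude_bias_pct": float(np.median(np.abs(np.mean(biases, axis=0)))),
        "n": n_seeds,
    }


def cv_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Segment-heterogeneity CV recovery at programmed cv in {0, 0.1, 0.2}.

    Observed CV^2 across segments is compared against the variance
    decomposition ``CV_true^2 + sigma_noise^2 / (T mu^2)``, with CV_true from
    the generator's per-segment amplitudes and sigma_noise estimated from the
    two-way (segment x trial) residual of the measured amplitude matrix.
    """
    recovered, predicted = [], []
    for cv in (0.0, 0.1, 0.2):
        obs2, pred2 = [], []
        for k in range(n_seeds):
            cfg = SceneConfig(
                n_cells=1, field_shape=(14, 48), duration_s=44.0, led_enabled=True,
                segment_heterogeneity_cv=cv, seed=_sub_seed(seed, 8, int(cv * 100) + k),
            )
            movie, daq, gt = simulate_movie(cfg)
            labels = gt.segment_label_maps[0]
            wimg = gt.cell_weights[0]
            gated = daq.gated_frames(cfg.frame_rate)
            flat = movie.data.reshape(movie.n_frames, -1)
            seg_base, miss = [], None
            for b in range(labels.max() + 1):
                w = np.where(labels == b, wimg, 0.0).ravel()
                raw = flat @ (w / w.sum())
                d = DffTrace.from_raw(raw, cfg.frame_rate, gating_intervals=daq.gating)
                seg_base.append(d.baseline)
                miss = d.missing
                times = d.time_s
            smap = segment_response_map(
                np.asarray(seg_base), times, triggers=daq.led_onsets, missing=miss
            )
            a = smap.per_trial
            mu = np.nanmean(a)
            # two-way residual: removes segment and (shared) trial effects
            resid = a - np.nanmean(a, axis=1, keepdims=True) - np.nanmean(a, axis=0) + mu
            s_count, t_count = a.shape
            sig2 = np.nansum(resid**2) / ((s_count - 1) * (t_count - 1))
            gt_means = gt.ipsp_segment_amplitude[0].mean(axis=0)
            cv_true2 = (np.std(gt_means, ddof=1) / gt_means.mean()) ** 2
            obs2.append(smap.cv**2)
            pred2.append(cv_true2 + sig2 / (t_count * mu**2))
        recovered.append(float(np.sqrt(np.mean(obs2))))
        predicted.append(float(np.sqrt(np.mean(pred2))))
    monotone = recovered[0] < recovered[1] < recovered[2]
    infl_err = max(
        abs(o / p - 1.0) for o, p in zip(np.array(recovered) ** 2, np.array(predicted) ** 2)
    )
    return {
        "recovered_cv_by_level": recovered,
        "predicted_cv_by_level": predicted,
        "monotone_fraction": float(monotone),
        "inflation_error_pct": float(infl_err * 100),
        "n": n_seeds,
    }


def plasticity_benchmark(seed: int = 0, n_runs: int = 10) -> dict:
    """Full pre/post pipeline: programmed +25% IPSP potentiation vs control."""
    wil_p, mix_p, pair_lr, ctrl_lr = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_runs):
            out = simulate_plasticity_experiment(seed=_sub_seed(seed, 9, k))
            wil_p.append(out["comparisons"]["pairing"].p_value)
            mix_p.append(out["group_difference"].p_value)
            pair_lr.extend(out["comparisons"]["pairing"].log_ratios.tolist())
            ctrl_lr.extend(out["comparisons"]["control"].log_ratios.tolist())
    return {
        "pairing_wilcoxon_p_median": float(np.median(wil_p)),
        "mixed_model_p_median": float(np.median(mix_p)),
        "pairing_median_log_ratio": float(np.median(pair_lr)),
        "control_median_log_ratio": float(np.median(ctrl_lr)),
        "n": n_runs,
    }


def plasticity_null_benchmark(seed: int = 0, n_runs: int = 200, alpha: float = 0.05) -> dict:
    """Type-I rate of the mixed-model group test under control-vs-control."""
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_runs):
            v, g, m, f = simulate_log_ratio_features(
                _sub_seed(seed, 10, k), effect={"pairing": 0.0, "control": 0.0}
            )
            rejections += group_difference(v, g, m, f).p_value < alpha
    lo = alpha - 1.96 * np.sqrt(alpha * (1 - alpha) / n_runs)
    hi = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / n_runs)
    return {
        "type1_rate": float(rejections / n_runs),
        "binomial_ci": [float(lo), float(hi)],
        "n": n_runs,
    }


def shuffle_uniformity_benchmark(seed: int = 0, n_seeds: int = 50, n_shuffles: int = 500) -> dict:
    """Percentile of the observed neighbor correlation in the within-mouse
    shuffle null must be uniform under exchangeable features."""
    from .plasticity import neighbor_correlation

    pcts = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 11, k))
        fovs = np.repeat([f"f{i}" for i in range(24)], 2)
        mice = np.repeat(["m0", "m1", "m2", "m3"], 12)
        res = neighbor_correlation(
            rng.normal(size=48), fovs, mice, n_shuffles=n_shuffles, seed=_sub_seed(seed, 12, k)
        )
        pcts.append(res.percentile)
    return {"ks_p_value": float(kstest(pcts, "uniform").pvalue), "n": n_seeds}
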