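"""End-to-end orchestration: simulate -> segment -> detect -> triggered ->
plasticity, with a run manifest recording inputs, config, seeds, per-stage
timing and warnings.

``analyze_fov`` is the workhorse: given a movie, its DAQ timeline and one
manually drawn mask per dendrite, it refines the masks, fits and segments
the dendrite paths, clusters segments into cells and runs trace
normalization, spike detection and IPSP extraction per cell.
``simulate_plasticity_experiment`` chains two simulated sessions per group
through the full pipeline (including cross-session cell matching) to
produce a :class:`~voltdend.plasticity.PlasticityComparison` per group and
a mixed-model group contrast.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .config import PipelineConfig
from .data import DaqTimeline, Movie
from .plasticity import (
    CellRecord,
    GroupDifference,
    PlasticityComparison,
    SessionRecord,
    compare_pre_post,
    group_difference,
    match_cells,
)
from .segmentation import (
    CellCluster,
    cluster_segments,
    extract_traces,
    fit_dendrite_path,
    refine_mask,
    segment_path,
)
from .synth import SceneConfig, simulate_movie
from .traces import DffTrace, SpikeTrain
from .triggered import ipsp_features, segment_response_map

__all__ = [
    "CellResult",
    "analyze_fov",
    "session_from_results",
    "simulate_plasticity_experiment",
    "simulate_log_ratio_features",
    "RunManifest",
    "run_end_to_end",
]


@dataclass
class CellResult:
    """One clustered cell with its derived signals and features."""

    cluster: CellCluster
    dff: DffTrace
    spikes: SpikeTrain
    mask: np.ndarray  # combined weight map of the member segments
    seg_dff: np.ndarray  # (n_member_segments, T)
    seg_baselines: np.ndarray
    ipsp_trials: np.ndarray  # per-trigger amplitude (NaN when flagged)
    seg_ipsp: np.ndarray = field(default_factory=lambda: np.zeros(0))  # per-segment mean
    cv: float = float("nan")

    @property
    def firing_rate_hz(self) -> float:
        span = self.dff.time_s[-1] - self.dff.time_s[0]
        return len(self.spikes) / span if span > 0 else float("nan")

    def spike_template(self, half_frames: int = 11) -> np.ndarray:
        """Mean -dF/F0 waveform around the detected spikes (+-25 ms)."""
        v = self.dff.values
        segs = [
            v[i - half_frames : i + half_frames + 1]
            for i in self.spikes.indices
            if i - half_frames >= 0 and i + half_frames + 1 <= len(v)
        ]
        return np.mean(segs, axis=0) if segs else np.zeros(2 * half_frames + 1)


def analyze_fov(
    movie: Movie,
    daq: DaqTimeline,
    masks: list[np.ndarray],
    cfg: PipelineConfig | None = None,
) -> list[CellResult]:
    """Segment, cluster and extract every cell in one field of view."""
    cfg = cfg or PipelineConfig()
    gated = daq.gated_frames(movie.frame_rate)
    all_traces, all_maps = [], []
    for mask in masks:
        refined = refine_mask(mask, cfg.mask_sigma_px)
        path = fit_dendrite_path(refined, movie.pixel_size_um)
        segset = segment_path(path, refined, cfg.segment_length_um)
        tr = extract_traces(movie, segset, gated_frames=gated)
        all_traces.append(tr)
        all_maps.extend(segset.segment_weight_map(i) for i in range(segset.n_segments))
    pooled = np.vstack(all_traces)
    clusters, _ = cluster_segments(
        pooled, movie.frame_rate, cfg.cluster_threshold_r, cfg.baseline_cutoff_hz
    )
    results = []
    for cl in clusters:
        dfft = DffTrace.from_raw(
            cl.trace,
            movie.frame_rate,
            gating_intervals=daq.gating,
            t0=float(movie.frame_times[0]),
            window_s=cfg.dff_window_s,
            cutoff_hz=cfg.baseline_cutoff_hz,
            order=cfg.baseline_order,
        )
        spikes = dfft.detect(
            threshold_sd=cfg.threshold_sd,
            peak_window_ms=cfg.peak_window_ms,
            pre_cut_ms=cfg.pre_cut_ms,
            post_cut_ms=cfg.post_cut_ms,
        )
        seg_dff, seg_base = [], []
        for sid in cl.segment_ids:
            st = DffTrace.from_raw(
                pooled[sid],
                movie.frame_rate,
                gating_intervals=daq.gating,
                t0=float(movie.frame_times[0]),
                window_s=cfg.dff_window_s,
                cutoff_hz=cfg.baseline_cutoff_hz,
                order=cfg.baseline_order,
            )
            seg_dff.append(st.values)
            seg_base.append(st.baseline)
        seg_dff, seg_base = np.asarray(seg_dff), np.asarray(seg_base)
        trials = np.array(
            [
                ipsp_features(
                    dfft.baseline, dfft.time_s, trig, cfg.ipsp_window_s, dfft.missing
                ).amplitude
                for trig in daq.led_onsets
            ]
        )
        cv = float("nan")
        seg_ipsp = np.zeros(0)
        if len(cl.segment_ids) >= 2 and len(daq.led_onsets):
            smap = segment_response_map(
                seg_base,
                dfft.time_s,
                triggers=daq.led_onsets,
                feature="ipsp",
                search_window_s=cfg.ipsp_window_s,
                missing=dfft.missing,
            )
            cv = smap.cv
            seg_ipsp = smap.per_segment
        mask_sum = np.sum([m for m in (all_maps[s] for s in cl.segment_ids)], axis=0)
        results.append(
            CellResult(
                cluster=cl,
                dff=dfft,
                spikes=spikes,
                mask=mask_sum,
                seg_dff=seg_dff,
                seg_baselines=seg_base,
                ipsp_trials=trials,
                seg_ipsp=seg_ipsp,
                cv=cv,
            )
        )
    return results


def session_from_results(
    results_by_fov: dict[str, list[CellResult]],
    mouse_of_fov: dict[str, str],
) -> SessionRecord:
    """Build a :class:`SessionRecord` from per-FOV analysis results."""
    cells = []
    for fov, results in results_by_fov.items():
        for k, r in enumerate(results):
            cells.append(
                CellRecord(
                    cell_id=f"{fov}/c{k}",
                    fov_id=fov,
                    mouse_id=mouse_of_fov[fov],
                    mask=r.mask,
                    corr_matrix=r.cluster.corr,
                    spike_template=r.spike_template(),
                    firing_rate_hz=r.firing_rate_hz,
                    ipsp_trial_amplitudes=r.ipsp_trials,
                    segment_map=r.seg_ipsp,
                    cv=r.cv,
                )
            )
    return SessionRecord(cells=cells)


def _plasticity_scene(
    amplitudes: list[float],
    factors: list[list[float]],
    duration_s: float,
    seed: int,
    scene_kwargs: dict | None = None,
) -> SceneConfig:
    kw = dict(
        n_cells=len(amplitudes),
        field_shape=(20, 48),
        duration_s=duration_s,
        led_enabled=True,
        led_start_s=1.5,
        led_period_s=2.0,
        ipsp_amplitude_per_cell=list(amplitudes),
        segment_factors=factors,
        seed=seed,
    )
    if scene_kwargs:
        kw.update(scene_kwargs)
    return SceneConfig(**kw)


def simulate_plasticity_experiment(
    seed: int,
    n_cells_per_group: int = 32,
    cells_per_fov: int = 2,
    mice_per_group: dict[str, int] | None = None,
    potentiation: dict[str, float] | None = None,
    duration_s: float = 42.0,
    base_amplitude: float = 0.079,
    cell_lognorm_sd: float = 0.4,
    mouse_lognorm_sd: float = 0.03,
    fov_lognorm_sd: float = 0.03,
    cfg: PipelineConfig | None = None,
    scene_kwargs: dict | None = None,
) -> dict:
    """Full pre/post plasticity experiment through the movie pipeline.

    For every group ('pairing': programmed IPSP scaling, 'control': none),
    pre and post sessions are simulated as movies, analyzed with
    :func:`analyze_fov`, matched with :func:`match_cells`, and compared with
    the paired Wilcoxon test; the groups are contrasted with the
    animal/FOV mixed model on the log amplitude ratios.
    """
    mice_per_group = mice_per_group or {"pairing": 4, "control": 2}
    potentiation = potentiation or {"pairing": 1.25, "control": 1.0}
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    n_fovs = n_cells_per_group // cells_per_fov
    comparisons: dict[str, PlasticityComparison] = {}
    lr_values, lr_groups, lr_mice, lr_fovs = [], [], [], []
    sub = 0
    for g_idx, (group, scale) in enumerate(sorted(potentiation.items())):
        mouse_names = [f"{group}_m{i}" for i in range(mice_per_group[group])]
        mouse_factor = {m: float(rng.lognormal(0.0, mouse_lognorm_sd)) for m in mouse_names}
        results_pre: dict[str, list[CellResult]] = {}
        results_post: dict[str, list[CellResult]] = {}
        mouse_of_fov: dict[str, str] = {}
        for f in range(n_fovs):
            fov = f"{group}_f{f}"
            mouse = mouse_names[f % len(mouse_names)]
            mouse_of_fov[fov] = mouse
            fov_factor = float(rng.lognormal(0.0, fov_lognorm_sd))
            amps = [
                base_amplitude
                * mouse_factor[mouse]
                * fov_factor
                * float(rng.lognormal(0.0, cell_lognorm_sd))
                for _ in range(cells_per_fov)
            ]
            # segment heterogeneity is a stable cell property: shared pre/post
            het_cv = (scene_kwargs or {}).get("segment_heterogeneity_cv", 0.13)
            factors = [
                np.clip(rng.normal(1.0, het_cv, size=40), 0.05, None).tolist()
                for _ in range(cells_per_fov)
            ]
            for session, amp_scale in (("pre", 1.0), ("post", scale)):
                sub += 1
                scene = _plasticity_scene(
                    [a * amp_scale for a in amps],
                    factors,
                    duration_s,
                    seed=int(np.random.SeedSequence([int(seed), 707, sub]).generate_state(1)[0] % (2**31)),
                    scene_kwargs=scene_kwargs,
                )
                movie, daq, gt = simulate_movie(scene)
                res = analyze_fov(movie, daq, gt.cell_weights, cfg)
                (results_pre if session == "pre" else results_post)[fov] = res
        pre_sess = session_from_results(results_pre, mouse_of_fov)
        post_sess = session_from_results(results_post, mouse_of_fov)
        pairs = match_cells(pre_sess, post_sess, threshold=cfg.match_threshold)
        comp = compare_pre_post(
            [p.pre.ipsp_trial_amplitudes for p in pairs],
            [p.post.ipsp_trial_amplitudes for p in pairs],
        )
        comparisons[group] = comp
        for pos, idx in enumerate(comp.log_ratio_cells):
            lr_values.append(float(comp.log_ratios[pos]))
            lr_groups.append(group)
            lr_mice.append(pairs[int(idx)].pre.mouse_id)
            lr_fovs.append(pairs[int(idx)].pre.fov_id)
    gd = group_difference(
        np.asarray(lr_values), np.asarray(lr_groups), np.asarray(lr_mice), np.asarray(lr_fovs)
    )
    return {
        "comparisons": comparisons,
        "group_difference": gd,
        "log_ratios": np.asarray(lr_values),
        "log_ratio_groups": np.asarray(lr_groups),
    }


def simulate_log_ratio_features(
    seed: int,
    n_cells_per_group: int = 32,
    cells_per_fov: int = 2,
    mice_per_group: dict[str, int] | None = None,
    effect: dict[str, float] | None = None,
    mouse_sd: float = 0.03,
    fov_sd: float = 0.03,
    residual_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature-level generator of per-cell log amplitude ratios.

    Used for statistical calibration at scales where simulating movies is
    unnecessary: ``lr = effect(group) + mouse + fov + noise`` with Gaussian
    random effects.  Returns ``(values, groups, mouse_ids, fov_ids)``.
    """
    mice_per_group = mice_per_group or {"pairing": 4, "control": 2}
    effect = effect or {"pairing": np.log(1.25), "control": 0.0}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 808]))
    values, groups, mice, fovs = [], [], [], []
    n_fovs = n_cells_per_group // cells_per_fov
    for group in sorted(effect):
        mouse_names = [f"{group}_m{i}" for i in range(mice_per_group[group])]
        m_eff = {m: rng.normal(0.0, mouse_sd) for m in mouse_names}
        for f in range(n_fovs):
            mouse = mouse_names[f % len(mouse_names)]
            f_eff = rng.normal(0.0, fov_sd)
            for _ in range(cells_per_fov):
                values.append(effect[group] + m_eff[mouse] + f_eff + rng.normal(0.0, residual_sd))
                groups.append(group)
                mice.append(mouse)
                fovs.append(f"{group}_f{f}")
    return (np.asarray(values), np.asarray(groups), np.asarray(mice), np.asarray(fovs))


# --------------------------------------------------------------------------
# end-to-end run with manifest


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_hashes: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "input_hashes": self.input_hashes,
                "stages": self.stages,
                "failure": self.failure,
            },
            indent=2,
        )


def _sha(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_end_to_end(
    cfg: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
    inputs: dict | None = None,
) -> RunManifest:
    """Run simulate -> segment -> detect -> triggered -> plasticity.

    With ``inputs`` (paths to a movie TIFF, DAQ JSON and mask TIFFs) the
    simulate stage is skipped and the files are loaded at the segment stage.
    Outputs and a manifest are written to ``out_dir``; a stage failure is
    recorded in the manifest (with partial outputs retained) and re-raised.
    Reruns with the same seed are bit-identical.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    manifest = RunManifest(config=json.loads(cfg.model_dump_json()), seed=seed, version=__version__)
    manifest.input_hashes["config"] = _sha(cfg.model_dump_json().encode())

    movie = daq = gt = None
    masks: list[np.ndarray] = []
    results: list[CellResult] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            status = "ok"
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    note = fn()
                msgs = [str(w.message) for w in wlist]
            except Exception as exc:
                manifest.stages.append(
                    {"name": name, "status": "failed", "seconds": time.perf_counter() - t0,
                     "warnings": [], "note": str(exc)}
                )
                manifest.failure = name
                (out / "manifest.json").write_text(manifest.to_json())
                raise
            manifest.stages.append(
                {"name": name, "status": status if note is not True else "ok",
                 "seconds": time.perf_counter() - t0, "warnings": msgs,
                 "note": note if isinstance(note, str) else ""}
            )

        return deco

    @stage("simulate")
    def _simulate():
        nonlocal movie, daq, gt, masks
        if inputs is not None:
            return "inputs provided; simulation skipped"
        movie, daq, gt = simulate_movie(cfg.scene, seed=seed)
        masks = gt.cell_weights
        vio.write_movie(out / "movie.tif", movie)
        vio.write_daq_json(out / "daq.json", daq)
        (out / "ground_truth.json").write_text(
            json.dumps({"spike_times": [t.tolist() for t in gt.spike_times],
                        "led": gt.led.tolist()})
        )
        manifest.input_hashes["movie"] = _sha(movie.data.tobytes())
        return None

    @stage("segment")
    def _segment():
        nonlocal movie, daq, masks, results
        if inputs is not None:
            movie = vio.read_movie(inputs["movie"])
            daq = vio.read_daq_json(inputs["daq"]) if "daq" in inputs else DaqTimeline(
                duration=movie.duration, frame_times=movie.frame_times
            )
            import tifffile

            masks = [tifffile.imread(p).astype(float) for p in inputs.get("masks", [])]
            manifest.input_hashes["movie"] = _sha(movie.data.tobytes())
        results = analyze_fov(movie, daq, masks, cfg)
        rows = []
        for ci, r in enumerate(results):
            for sid in r.cluster.segment_ids:
                rows.append({"cell_id": ci, "segment_id": int(sid)})
        pd.DataFrame(rows).to_csv(out / "segments.csv", index=False)
        return None

    @stage("detect")
    def _detect():
        for ci, r in enumerate(results):
            vio.write_spikes_csv(out / f"spikes_cell{ci}.csv", r.spikes)
            vio.write_trace_csv(out / f"dff_cell{ci}.csv", r.dff.time_s, r.dff.values, "neg_dff")
        return None

    @stage("triggered")
    def _triggered():
        rows = []
        for ci, r in enumerate(results):
            for j, amp in enumerate(r.ipsp_trials):
                rows.append({"cell_id": ci, "trial": j, "ipsp_amplitude": amp})
        pd.DataFrame(rows).to_csv(out / "ipsp_trials.csv", index=False)
        pd.DataFrame(
            [{"cell_id": ci, "cv": r.cv, "n_spikes": len(r.spikes),
              "rate_hz": r.firing_rate_hz} for ci, r in enumerate(results)]
        ).to_csv(out / "cell_features.csv", index=False)
        return None

    @stage("plasticity")
    def _plasticity():
        # single-session stability check: first vs second half of the trials
        usable = [r for r in results if np.isfinite(r.ipsp_trials).sum() >= 4]
        if len(usable) < 6:
            return "skipped: fewer than 6 cells with enough trials for a stability test"
        pre = [r.ipsp_trials[: len(r.ipsp_trials) // 2] for r in usable]
        post = [r.ipsp_trials[len(r.ipsp_trials) // 2 :] for r in usable]
        comp = compare_pre_post(pre, post)
        (out / "stability.json").write_text(
            json.dumps({"p_value": comp.p_value, "n": comp.n,
                        "median_log_ratio": float(np.median(comp.log_ratios))})
        )
        return None

    manifest.input_hashes["outputs"] = _sha(
        b"".join(
            sorted(
                p.read_bytes()
                for p in out.glob("*.csv")
            )
        )
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
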