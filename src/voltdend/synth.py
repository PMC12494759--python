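"""Synthetic two-photon voltage-imaging data with full ground truth.

The generator emulates the statistical structure of GEVI recordings from
Purkinje-cell dendrites so that every analysis stage can be validated
against known truth:

* dendrites as cubic bands with per-pixel baseline brightness,
* negative-polarity voltage-to-fluorescence coupling (depolarization dims
  the sensor), linear in the subthreshold regime,
* Poisson complex spikes (default 1.3 Hz) with a difference-of-exponentials
  waveform whose FWHM defaults to 10.5 ms,
* optogenetically evoked IPSPs with an alpha-like kernel peaking 85.4 ms
  after the LED pulse, graded with LED intensity, heterogeneous across
  4.8 um dendritic segments,
* shared-parent "microzone" spike sources with timing jitter and failures,
* slow Ornstein-Uhlenbeck subthreshold drift, multi-exponential
  photobleaching, Gaussian shot-noise approximation (sd ~ sqrt(brightness)),
* detector-gating blanks around every LED pulse (frames held at 0),
* a 20 kHz DAQ timeline carrying LED, gating, sensory and frame-sync events.

Identical seeds reproduce outputs bit-exactly: one master ``SeedSequence``
is split into fixed, named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.spatial import cKDTree

from .data import DaqTimeline, GroundTruth, Movie
from .segmentation import arc_segment_edges

__all__ = [
    "DendriteSpec",
    "SceneConfig",
    "DendriteRender",
    "render_dendrite",
    "simulate_movie",
    "simulate_spike_trains",
    "calibrate_noise_for_dprime",
    "cs_kernel_taus",
    "ipsp_kernel_taus",
    "SensorParams",
    "ProtocolSegment",
    "ClampProtocol",
    "simulate_clamp_trace",
]

DAQ_RATE = 20_000.0


# --------------------------------------------------------------------------
# configuration


class DendriteSpec(BaseModel):
    """One dendrite: a cubic path in image coordinates (um).

    ``y(x) = c0 + c1 x + c2 x^2 + c3 x^3`` for x in ``x_range_um``.
    """

    model_config = ConfigDict(extra="forbid")

    coeffs_um: tuple[float, float, float, float]
    x_range_um: tuple[float, float]
    width_um: float = 4.0

    @model_validator(mode="after")
    def _check(self) -> "DendriteSpec":
        if self.x_range_um[1] <= self.x_range_um[0]:
            raise ValueError("x_range_um must be increasing")
        if self.width_um < 0:
            raise ValueError("width_um must be >= 0")
        return self


class SceneConfig(BaseModel):
    """Everything the movie simulator needs; defaults follow the recording
    conditions the analysis was designed for (440 Hz, 0.8 um/px, 1.3 Hz
    complex spikes of -dF/F0 = 0.312 and 10.5 ms FWHM, IPSPs peaking 85.4 ms
    after the LED with base amplitude 0.079)."""

    model_config = ConfigDict(extra="forbid")

    n_cells: int = Field(1, ge=1)
    field_shape: tuple[int, int] = (30, 254)  # (H, W) pixels
    pixel_size_um: float = Field(0.8, gt=0)
    frame_rate: float = Field(440.0, gt=0)
    duration_s: float = Field(60.0, gt=0)
    dendrites: Optional[list[DendriteSpec]] = None  # None -> auto layout
    brightness: float = Field(30.0, gt=0)  # mean photons/px/frame on the dendrite
    background: float = Field(1.0, ge=0)

    # complex spikes
    cs_rate_hz: float = Field(1.3, ge=0)
    cs_amplitude: float = Field(0.312, ge=0)  # -dF/F0 fraction at the peak
    cs_rise_ms: float = Field(1.0, gt=0)
    cs_fwhm_ms: float = Field(10.5, gt=0)
    cs_spike_times: Optional[list[list[float]]] = None  # forced, per cell (s)

    # optogenetic stimulation / IPSPs
    led_enabled: bool = False
    led_start_s: float = Field(1.5, ge=0)
    led_period_s: float = Field(2.0, gt=0)
    led_duration_ms: float = Field(2.0, gt=0)
    led_levels: list[float] = Field(default_factory=lambda: [1.0])
    ipsp_amplitude: float = Field(0.079, ge=0)  # -dF/F0 magnitude at level 1
    ipsp_amplitude_per_cell: Optional[list[float]] = None  # overrides ipsp_amplitude
    ipsp_time_to_peak_ms: float = Field(85.4, gt=0)
    ipsp_decay_ms: float = Field(120.0, gt=0)
    ipsp_trial_cv: float = Field(0.10, ge=0)
    segment_heterogeneity_cv: float = Field(0.13, ge=0)
    segment_factors: Optional[list[list[float]]] = None  # per cell, per 4.8 um block;
    # overrides the random draw (heterogeneity is a stable property of a dendrite,
    # so repeated sessions of the same cell should share its factors)
    segment_length_um: float = Field(4.8, gt=0)

    # sensory (air-puff) stimulation evoking complex spikes
    sensory_enabled: bool = False
    sensory_start_s: float = Field(1.0, ge=0)
    sensory_period_s: float = Field(2.0, gt=0)
    sensory_duration_ms: float = Field(25.0, gt=0)
    sensory_spike_prob: float = Field(0.8, ge=0, le=1)
    sensory_latency_ms: float = Field(15.0, ge=0)
    sensory_jitter_ms: float = Field(3.0, ge=0)

    # microzone structure
    microzone_parent: Optional[list[int]] = None  # cell -> parent source id
    microzone_jitter_ms: float = Field(2.0, ge=0)
    microzone_failure_prob: float = Field(0.0, ge=0, le=1)

    # nuisance processes
    bleach_enabled: bool = True
    bleach_amplitudes: list[float] = Field(default_factory=lambda: [0.85, 0.10, 0.05])
    bleach_taus_s: list[float] = Field(default_factory=lambda: [1e6, 200.0, 30.0])
    drift_sd: float = Field(0.03, ge=0)  # -dF/F0 units; shared subthreshold fluctuation
    drift_cutoff_hz: float = Field(0.5, gt=0)
    noise_scale: float = Field(1.0, ge=0)  # pixel sd = noise_scale * sqrt(brightness)
    gating_pad_ms: float = Field(1.0, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneConfig":
        if self.duration_s * self.frame_rate < 2:
            raise ValueError("duration_s: need at least 2 frames")
        if len(self.bleach_amplitudes) != len(self.bleach_taus_s):
            raise ValueError("bleach_amplitudes and bleach_taus_s must have equal length")
        if any(t <= 0 for t in self.bleach_taus_s):
            raise ValueError("bleach_taus_s must be positive")
        if self.microzone_parent is not None and len(self.microzone_parent) != self.n_cells:
            raise ValueError("microzone_parent must list one parent per cell")
        if self.cs_spike_times is not None and len(self.cs_spike_times) != self.n_cells:
            raise ValueError("cs_spike_times must list one train per cell")
        if not self.led_levels:
            raise ValueError("led_levels must be non-empty")
        if (
            self.ipsp_amplitude_per_cell is not None
            and len(self.ipsp_amplitude_per_cell) != self.n_cells
        ):
            raise ValueError("ipsp_amplitude_per_cell must list one amplitude per cell")
        if self.segment_factors is not None and len(self.segment_factors) != self.n_cells:
            raise ValueError("segment_factors must list one factor set per cell")
        return self

    def resolved_dendrites(self) -> list[DendriteSpec]:
        """Default layout: horizontal bands evenly spaced in the field."""
        if self.dendrites is not None:
            if len(self.dendrites) != self.n_cells:
                raise ValueError("dendrites must list one path per cell")
            return self.dendrites
        h, w = self.field_shape
        ps = self.pixel_size_um
        margin = 3.0  # um, keeps the band inside the field
        xs = (margin, (w - 1) * ps - margin)
        out = []
        for i in range(self.n_cells):
            y = (i + 1) / (self.n_cells + 1) * (h - 1) * ps
            out.append(DendriteSpec(coeffs_um=(y, 0.0, 0.0, 0.0), x_range_um=xs, width_um=4.0))
        return out


# --------------------------------------------------------------------------
# waveform kernels


def _diff_exp(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Difference of exponentials, zero for t < 0, peak normalized to 1."""
    t = np.asarray(t, dtype=float)
    t_pk = np.log(tau_d / tau_r) / (1 / tau_r - 1 / tau_d)
    peak = np.exp(-t_pk / tau_d) - np.exp(-t_pk / tau_r)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = np.exp(-t[pos] / tau_d) - np.exp(-t[pos] / tau_r)
    return out / peak


def _diff_exp_fwhm(tau_r: float, tau_d: float) -> float:
    t = np.linspace(0, 12 * tau_d, 20000)
    y = _diff_exp(t, tau_r, tau_d)
    above = np.flatnonzero(y >= 0.5)
    return t[above[-1]] - t[above[0]]


@lru_cache(maxsize=32)
def cs_kernel_taus(rise_ms: float, fwhm_ms: float) -> tuple[float, float]:
    """Rise/decay time constants (ms) of the complex-spike kernel.

    The decay is solved numerically so the difference-of-exponentials
    waveform has the requested FWHM.
    """
    f = lambda td: _diff_exp_fwhm(rise_ms, td) - fwhm_ms
    tau_d = brentq(f, rise_ms * 1.01 + fwhm_ms * 0.05, fwhm_ms * 10)
    return rise_ms, float(tau_d)


@lru_cache(maxsize=32)
def ipsp_kernel_taus(time_to_peak_ms: float, decay_ms: float) -> tuple[float, float]:
    """Rise/decay time constants (ms) of the alpha-like IPSP kernel."""
    if decay_ms <= time_to_peak_ms:
        raise ValueError("ipsp_decay_ms must exceed ipsp_time_to_peak_ms")
    t_peak = lambda tr: np.log(decay_ms / tr) / (1 / tr - 1 / decay_ms)
    f = lambda tr: t_peak(tr) - time_to_peak_ms
    tau_r = brentq(f, 1e-3, decay_ms * (1 - 1e-6))
    return float(tau_r), decay_ms


def _add_kernel(
    v: np.ndarray,
    t_grid: np.ndarray,
    event_t: float,
    amp: float,
    tau_r_s: float,
    tau_d_s: float,
    peak_aligned: bool,
) -> None:
    """Add one kernel in place, evaluated only on its support (for speed)."""
    t_pk = np.log(tau_d_s / tau_r_s) / (1 / tau_r_s - 1 / tau_d_s)
    onset = event_t - (t_pk if peak_aligned else 0.0)
    dt = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 1.0
    i0 = max(0, int(np.floor((onset - t_grid[0]) / dt)))
    i1 = min(len(t_grid), int(np.ceil((onset + 10 * tau_d_s - t_grid[0]) / dt)) + 1)
    if i1 <= i0:
        return
    v[i0:i1] += amp * _diff_exp(t_grid[i0:i1] - onset, tau_r_s, tau_d_s)


# --------------------------------------------------------------------------
# dendrite rendering


@dataclass
class DendriteRender:
    """Rasterized dendrite: pixel weights plus arc-length coordinates."""

    weights: np.ndarray  # (H, W) in [0, 1]
    arc_um: np.ndarray  # (H, W) arc position of nearest path point (NaN off-band)
    length_um: float


def render_dendrite(
    coeffs_um: Sequence[float],
    x_range_um: tuple[float, float],
    width_um: float,
    field_shape: tuple[int, int],
    pixel_size_um: float,
) -> DendriteRender:
    """Rasterize a cubic dendrite path into a binary-band weight image.

    Weights are 1 within ``width_um/2`` of the path (plus the rasterized
    path itself, so a width of 0 leaves a single-pixel-wide trace) and 0
    elsewhere.  Raises if the path comes within ``width_um/2`` of the field
    edge.
    """
    h, w = field_shape
    ps = pixel_size_um
    x = np.linspace(x_range_um[0], x_range_um[1], max(64, int(np.ceil((x_range_um[1] - x_range_um[0]) / (ps / 4)))))
    y = np.polynomial.polynomial.polyval(x, np.asarray(coeffs_um, dtype=float))
    half = width_um / 2
    if (
        x.min() - half < -ps / 2
        or x.max() + half > (w - 0.5) * ps
        or y.min() - half < -ps / 2
        or y.max() + half > (h - 0.5) * ps
    ):
        raise ValueError("dendrite path exits the field (needs width/2 margin)")
    pts = np.stack([x, y], axis=1)
    seg = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    cols, rows = np.meshgrid(np.arange(w) * ps, np.arange(h) * ps)
    tree = cKDTree(pts)
    dist, idx = tree.query(np.stack([cols.ravel(), rows.ravel()], axis=1))
    dist = dist.reshape(h, w)
    nearest_arc = arc[idx].reshape(h, w)
    weights = (dist <= half).astype(float)
    # rasterized centre line: guarantees support even at width 0
    ci = np.clip(np.round(x / ps).astype(int), 0, w - 1)
    ri = np.clip(np.round(y / ps).astype(int), 0, h - 1)
    weights[ri, ci] = 1.0
    arc_map = np.where(weights > 0, nearest_arc, np.nan)
    return DendriteRender(weights=weights, arc_um=arc_map, length_um=float(arc[-1]))


# --------------------------------------------------------------------------
# event generation


def _poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_spike_trains(
    config: SceneConfig, seed: int | None = None
) -> tuple[list[np.ndarray], dict[int, np.ndarray]]:
    """Draw complex-spike times for every cell (no movie rendering).

    Cells sharing a microzone parent receive the parent's Poisson events,
    each independently dropped with the failure probability and jittered by
    a centered Gaussian.  Returns ``(per-cell spike times, parent events)``.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 101])
    rng = np.random.default_rng(ss)
    parents = config.microzone_parent or list(range(config.n_cells))
    fail = config.microzone_failure_prob
    rate = config.cs_rate_hz / max(1e-12, 1 - fail) if fail < 1 else 0.0
    parent_events: dict[int, np.ndarray] = {}
    for p in sorted(set(parents)):
        parent_events[p] = _poisson_train(rng, rate, config.duration_s)
    trains = []
    for c in range(config.n_cells):
        if config.cs_spike_times is not None:
            t = np.sort(np.asarray(config.cs_spike_times[c], dtype=float))
        else:
            ev = parent_events[parents[c]]
            keep = rng.uniform(size=len(ev)) >= fail
            t = ev[keep] + rng.normal(0.0, config.microzone_jitter_ms / 1000.0, size=keep.sum())
            if config.sensory_enabled:
                onsets = _stim_onsets(config.sensory_start_s, config.sensory_period_s, config.duration_s)
                evoked = onsets[rng.uniform(size=len(onsets)) < config.sensory_spike_prob]
                evoked = evoked + config.sensory_latency_ms / 1000.0 + rng.normal(
                    0.0, config.sensory_jitter_ms / 1000.0, size=len(evoked)
                )
                t = np.concatenate([t, evoked])
            t = np.sort(t[(t > 0.05) & (t < config.duration_s - 0.05)])
            # enforce strictly increasing (degenerate coincidences are dropped)
            if len(t) > 1:
                t = t[np.concatenate([[True], np.diff(t) > 1e-6])]
        trains.append(t)
    return trains, parent_events


def _stim_onsets(start: float, period: float, duration: float) -> np.ndarray:
    """Stimulus onsets on the 20 kHz DAQ grid, leaving room for the response."""
    t = np.arange(start, duration - 0.35, period)
    return np.round(t * DAQ_RATE) / DAQ_RATE


def _bleach_curve(config: SceneConfig, t: np.ndarray) -> np.ndarray:
    if not config.bleach_enabled:
        return np.ones_like(t)
    a = np.asarray(config.bleach_amplitudes, dtype=float)
    tau = np.asarray(config.bleach_taus_s, dtype=float)
    curve = (a[:, None] * np.exp(-t[None, :] / tau[:, None])).sum(axis=0)
    return curve / curve[0]


def _ou_drift(rng: np.random.Generator, n: int, dt: float, sd: float, cutoff_hz: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    tau = 1.0 / (2 * np.pi * cutoff_hz)
    rho = np.exp(-dt / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], innov)


# --------------------------------------------------------------------------
# movie simulation


def simulate_movie(
    config: SceneConfig, seed: int | None = None
) -> tuple[Movie, DaqTimeline, GroundTruth]:
    """Render a full synthetic movie plus DAQ timeline plus ground truth.

    The per-pixel forward model for cell ``c`` with weight image ``w`` is::

        F_p(t) = background
               + B * bleach(t) * w_p * (1 - v_cs(t) - drift(t) + g_p * u(t))
               + noise_p(t)

    where ``v_cs`` is the complex-spike depolarization (in -dF/F0 units,
    kernel peak aligned to the ground-truth spike time), ``u(t) >= 0`` is
    the IPSP hyperpolarization magnitude and ``g_p`` its per-segment
    heterogeneity factor.  Noise is Gaussian with per-pixel sd
    ``noise_scale * sqrt(mean brightness)``.  Frames whose exposure overlaps
    a gating interval (LED +- gating_pad_ms) are blanked to 0.
    """
    seed = config.seed if seed is None else seed
    n_frames = int(round(config.duration_s * config.frame_rate))
    h, w = config.field_shape
    frame_times = np.arange(n_frames) / config.frame_rate
    t_mid = frame_times + 0.5 / config.frame_rate

    trains, parent_events = simulate_spike_trains(config, seed)
    ss = np.random.SeedSequence([int(seed), 202])
    rng_drift, rng_het, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    # stimulation schedule
    if config.led_enabled:
        led_on = _stim_onsets(config.led_start_s, config.led_period_s, config.duration_s)
        levels = np.array(
            [config.led_levels[i % len(config.led_levels)] for i in range(len(led_on))]
        )
        led = np.stack([led_on, led_on + config.led_duration_ms / 1000.0, levels], axis=1)
        pad = config.gating_pad_ms / 1000.0
        gating = np.stack([led[:, 0] - pad, led[:, 1] + pad], axis=1)
    else:
        led = np.zeros((0, 3))
        gating = np.zeros((0, 2))
    if config.sensory_enabled:
        s_on = _stim_onsets(config.sensory_start_s, config.sensory_period_s, config.duration_s)
        sensory = np.stack([s_on, s_on + config.sensory_duration_ms / 1000.0], axis=1)
    else:
        sensory = np.zeros((0, 2))

    bleach = _bleach_curve(config, t_mid)
    cs_tr, cs_td = cs_kernel_taus(config.cs_rise_ms, config.cs_fwhm_ms)
    ip_tr, ip_td = ipsp_kernel_taus(config.ipsp_time_to_peak_ms, config.ipsp_decay_ms)

    # per-trial IPSP gain, shared across cells/segments (stimulus efficacy)
    n_trig = len(led)
    trial_factors = (
        np.clip(rng_het.normal(1.0, config.ipsp_trial_cv, size=n_trig), 0.0, None)
        if n_trig
        else np.zeros(0)
    )

    # the movie is a low-rank signal (sum of per-cell rank-1 terms) plus
    # noise; composing it as one float32 matrix product keeps rendering fast
    temporal_cols: list[np.ndarray] = [np.ones(n_frames)]
    spatial_rows: list[np.ndarray] = [np.full(h * w, config.background)]
    dends = config.resolved_dendrites()
    voltage = np.zeros((config.n_cells, n_frames))
    gains = np.zeros(config.n_cells)
    ipsp_amp_gt: list[np.ndarray] = []
    seg_edges_gt: list[np.ndarray] = []
    seg_factors_gt: list[np.ndarray] = []
    seg_labels_gt: list[np.ndarray] = []
    ipsp_gain = np.zeros(config.n_cells)
    cell_weights: list[np.ndarray] = []
    mean_brightness = np.full((h, w), config.background, dtype=np.float64)

    for c, spec in enumerate(dends):
        render = render_dendrite(
            spec.coeffs_um, spec.x_range_um, spec.width_um, (h, w), config.pixel_size_um
        )
        wimg = render.weights
        cell_weights.append(wimg)
        mean_brightness += config.brightness * wimg

        v_cs = np.zeros(n_frames)
        for st in trains[c]:
            _add_kernel(v_cs, t_mid, st, config.cs_amplitude, cs_tr / 1000, cs_td / 1000, True)
        drift = _ou_drift(
            rng_drift, n_frames, 1 / config.frame_rate, config.drift_sd, config.drift_cutoff_hz
        )

        # segment heterogeneity of the IPSP along the arc
        edges = arc_segment_edges(render.length_um, config.segment_length_um)
        drawn = np.clip(
            rng_het.normal(1.0, config.segment_heterogeneity_cv, size=len(edges) - 1), 0.05, None
        )
        if config.segment_factors is not None:
            given = np.asarray(config.segment_factors[c], dtype=float)
            if len(given) < len(edges) - 1:
                raise ValueError(
                    f"segment_factors[{c}] has {len(given)} entries; "
                    f"cell {c} has {len(edges) - 1} segments"
                )
            factors = given[: len(edges) - 1]
        else:
            factors = drawn
        g_img = np.zeros((h, w))
        on = wimg > 0
        seg_of_pix = np.clip(
            np.searchsorted(edges, render.arc_um[on], side="right") - 1, 0, len(edges) - 2
        )
        g_img[on] = factors[seg_of_pix]
        label_map = np.full((h, w), -1, dtype=int)
        label_map[on] = seg_of_pix

        cell_amp = (
            config.ipsp_amplitude_per_cell[c]
            if config.ipsp_amplitude_per_cell is not None
            else config.ipsp_amplitude
        )
        u = np.zeros(n_frames)
        amps = np.zeros((n_trig, len(factors)))
        for j in range(n_trig):
            a_j = cell_amp * led[j, 2] * trial_factors[j]
            _add_kernel(u, t_mid, led[j, 0], a_j, ip_tr / 1000, ip_td / 1000, False)
            amps[j] = a_j * factors
        ipsp_amp_gt.append(amps)
        seg_edges_gt.append(edges)
        seg_factors_gt.append(factors)
        seg_labels_gt.append(label_map)

        base = 1.0 - v_cs - drift
        temporal_cols.append(bleach * base)
        spatial_rows.append(config.brightness * wimg.ravel())
        temporal_cols.append(bleach * u)
        spatial_rows.append(config.brightness * (wimg * g_img).ravel())
        s1 = wimg.sum()
        s2 = (wimg**2).sum()
        g_hat = (wimg**2 * g_img).sum() / s2
        voltage[c] = v_cs + drift - g_hat * u
        gains[c] = config.brightness * s2 / s1
        ipsp_gain[c] = g_hat

    a = np.stack(temporal_cols, axis=1).astype(np.float32)
    b = np.stack(spatial_rows, axis=0).astype(np.float32)
    movie = (a @ b).reshape(n_frames, h, w)
    if config.noise_scale > 0:
        sd = (config.noise_scale * np.sqrt(mean_brightness)).astype(np.float32)
        noise = rng_noise.standard_normal((n_frames, h, w), dtype=np.float32)
        noise *= sd
        movie += noise

    daq = DaqTimeline(
        duration=config.duration_s,
        frame_times=frame_times,
        led=led,
        gating=gating,
        sensory=sensory,
    )
    gated = daq.gated_frames(config.frame_rate)
    movie[gated] = 0.0

    gt = GroundTruth(
        spike_times=trains,
        voltage=voltage,
        gain=gains,
        background=config.background,
        bleach_curve=bleach,
        gating_intervals=gating,
        parent_events=parent_events,
        led=led,
        sensory_times=sensory[:, 0] if len(sensory) else np.zeros(0),
        ipsp_segment_amplitude=ipsp_amp_gt,
        segment_edges_um=seg_edges_gt,
        segment_factors=seg_factors_gt,
        trial_factors=trial_factors,
        cell_weights=cell_weights,
        segment_label_maps=seg_labels_gt,
        ipsp_gain=ipsp_gain,
    )
    mv = Movie(
        data=movie,
        frame_rate=config.frame_rate,
        pixel_size_um=config.pixel_size_um,
        frame_times=frame_times,
    )
    return mv, daq, gt


def calibrate_noise_for_dprime(config: SceneConfig, target_dprime: float = 5.0) -> float:
    """Pixel-noise scale that puts whole-dendrite spike detectability at
    ``target_dprime``.

    The mask-weighted trace of a dendrite with weights ``w`` and pixel
    brightness ``B_p`` has noise sd ``scale * sqrt(sum w^2 B) / sum w``;
    dividing by the trace mean gives the -dF/F0 background sd, to which the
    subthreshold drift adds in quadrature.  Solving
    ``cs_amplitude / sigma_B = d'`` for the scale is a closed form.
    """
    if target_dprime <= 0:
        raise ValueError("target_dprime must be positive")
    # effective spike amplitude on the frame grid: the sharp kernel peak is
    # attenuated by frame sampling, and that is the amplitude d' sees
    tr, td = cs_kernel_taus(config.cs_rise_ms, config.cs_fwhm_ms)
    t_pk = np.log(td / tr) / (1 / tr - 1 / td)
    dt_ms = 1000.0 / config.frame_rate
    phases = np.linspace(0, dt_ms, 33)
    grid = np.arange(-2 * dt_ms, 8 * td, dt_ms)
    peaks = [np.max(_diff_exp(grid + ph + t_pk, tr, td)) for ph in phases]
    amp_eff = config.cs_amplitude * float(np.mean(peaks))
    sig2_needed = (amp_eff / target_dprime) ** 2 - config.drift_sd**2
    if sig2_needed <= 0:
        raise ValueError("drift alone exceeds the requested background sd")
    scales = []
    for spec in config.resolved_dendrites():
        render = render_dendrite(
            spec.coeffs_um,
            spec.x_range_um,
            spec.width_um,
            config.field_shape,
            config.pixel_size_um,
        )
        wimg = render.weights
        bright = config.background + config.brightness * wimg
        s1 = wimg.sum()
        mu_f = config.brightness * (wimg**2).sum() / s1 + config.background
        sigma_trace_unit = np.sqrt((wimg**2 * bright).sum()) / s1  # per unit scale
        scales.append(np.sqrt(sig2_needed) * mu_f / sigma_trace_unit)
    return float(np.mean(scales))


# --------------------------------------------------------------------------
# voltage-clamp trace simulation


class SensorParams(BaseModel):
    """Linear F-V coupling with first-order on/off kinetics.

    ``slope_per_mv`` is dF/F0 per mV (negative: the sensor dims on
    depolarization).  ``tau_on_ms`` governs relaxation toward a dimmer
    steady state (depolarization), ``tau_off_ms`` the return.
    """

    model_config = ConfigDict(extra="forbid")

    slope_per_mv: float = -0.015
    v_ref_mv: float = -70.0
    f0: float = 1.0
    tau_on_ms: float = Field(1.5, gt=0)
    tau_off_ms: float = Field(3.0, gt=0)

    def steady_state(self, v_mv: np.ndarray) -> np.ndarray:
        return self.f0 * (1.0 + self.slope_per_mv * (np.asarray(v_mv, dtype=float) - self.v_ref_mv))


class ProtocolSegment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["spike_waveform", "spike_train", "step", "burst"]
    start_s: float = Field(..., ge=0)
    fwhm_ms: float = 2.0
    amplitude_mv: float = 100.0
    n_spikes: int = 1
    freq_hz: float = 2.0
    step_levels_mv: list[float] = Field(default_factory=list)
    step_duration_s: float = 1.0
    step_gap_s: float = 1.5
    sub_depol_mv: float = 24.0

    def duration(self) -> float:
        if self.kind == "spike_waveform":
            return 6 * self.fwhm_ms / 1000.0
        if self.kind in ("spike_train", "burst"):
            return (self.n_spikes - 1) / self.freq_hz + 6 * self.fwhm_ms / 1000.0 + (
                0.05 if self.kind == "burst" else 0.0
            )
        if self.kind == "step":
            return len(self.step_levels_mv) * (self.step_duration_s + self.step_gap_s)
        raise ValueError(f"unknown protocol segment kind: {self.kind}")


class ClampProtocol(BaseModel):
    model_config = ConfigDict(extra="forbid")

    segments: list[ProtocolSegment]
    hold_mv: float = -70.0
    duration_s: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ClampProtocol":
        spans = sorted((s.start_s, s.start_s + s.duration()) for s in self.segments)
        for (a0, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("protocol segments overlap")
        return self

    def total_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        if not self.segments:
            return 1.0
        return max(s.start_s + s.duration() for s in self.segments) + 0.5


def _gaussian_spike(t: np.ndarray, center: float, fwhm_ms: float, amp_mv: float) -> np.ndarray:
    sd = fwhm_ms / 1000.0 / (2 * np.sqrt(2 * np.log(2)))
    return amp_mv * np.exp(-0.5 * ((t - center) / sd) ** 2)


def build_command_voltage(
    protocol: ClampProtocol, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render the command-voltage trace of a protocol (returns ``t, V``)."""
    n = int(round(protocol.total_duration() * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.full(n, protocol.hold_mv)
    for seg in protocol.segments:
        if seg.kind == "spike_waveform":
            v += _gaussian_spike(t, seg.start_s + 3 * seg.fwhm_ms / 1000, seg.fwhm_ms, seg.amplitude_mv)
        elif seg.kind == "spike_train":
            for k in range(seg.n_spikes):
                c = seg.start_s + 3 * seg.fwhm_ms / 1000 + k / seg.freq_hz
                v += _gaussian_spike(t, c, seg.fwhm_ms, seg.amplitude_mv)
        elif seg.kind == "burst":
            a, b = seg.start_s, seg.start_s + seg.duration()
            v += np.where((t >= a) & (t < b), seg.sub_depol_mv, 0.0)
            for k in range(seg.n_spikes):
                c = a + 3 * seg.fwhm_ms / 1000 + k / seg.freq_hz
                v += _gaussian_spike(t, c, seg.fwhm_ms, seg.amplitude_mv)
        elif seg.kind == "step":
            for k, level in enumerate(seg.step_levels_mv):
                a = seg.start_s + k * (seg.step_duration_s + seg.step_gap_s)
                b = a + seg.step_duration_s
                v = np.where((t >= a) & (t < b), level, v)
        else:  # pragma: no cover - pydantic already rejects unknown kinds
            raise ValueError(f"unknown protocol segment kind: {seg.kind}")
    return t, v


def simulate_clamp_trace(
    protocol: ClampProtocol,
    sensor: SensorParams | None = None,
    sample_rate: float = 10_000.0,
    noise_sd: float = 0.0,
    bleach_taus_s: Sequence[float] | None = None,
    bleach_amplitudes: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the fluorescence readout of a voltage-clamp protocol.

    The sensor follows its linear F-V steady state through a first-order
    relaxation (``tau_on`` toward dimmer states, ``tau_off`` back), is
    multiplied by an optional multi-exponential bleach curve, and Gaussian
    noise is added.  Returns ``(fluorescence, command_voltage, times)`` on a
    common time base.
    """
    if sample_rate < 1000:
        raise ValueError("sample_rate must be >= 1 kHz")
    sensor = sensor or SensorParams()
    t, v = build_command_voltage(protocol, sample_rate)
    target = sensor.steady_state(v)
    dt = 1.0 / sample_rate
    a_on = np.exp(-dt / (sensor.tau_on_ms / 1000.0))
    a_off = np.exp(-dt / (sensor.tau_off_ms / 1000.0))
    f = np.empty_like(target)
    f[0] = target[0]
    for i in range(1, len(f)):
        a = a_on if target[i] < f[i - 1] else a_off
        f[i] = target[i] + (f[i - 1] - target[i]) * a
    if bleach_taus_s is not None:
        a = np.asarray(bleach_amplitudes if bleach_amplitudes is not None else [1.0] * len(bleach_taus_s), dtype=float)
        tau = np.asarray(bleach_taus_s, dtype=float)
        curve = (a[:, None] * np.exp(-t[None, :] / tau[:, None])).sum(axis=0)
        f = f * (curve / curve[0])
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
        f = f + rng.normal(0.0, noise_sd, size=len(f))
    return f, v, t
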