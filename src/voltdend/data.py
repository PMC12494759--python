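"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Times are seconds in the acquisition (DAQ) domain; latencies relative to a
  trigger are milliseconds.
* Movies are frame-major ``(T, H, W)`` float32 arrays.  Pixel (0, 0) is the
  top-left corner; pixel centers sit on integer coordinates and physical
  lengths are obtained through ``pixel_size_um``.
* Fluorescence polarity: the sensor dims on depolarization, so analysis
  signals are reported as ``-dF/F0`` (positive = depolarization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Movie", "DaqTimeline", "GroundTruth"]


@dataclass
class Movie:
    """A fluorescence movie with its acquisition geometry.

    Attributes
    ----------
    data : (T, H, W) float32 array
        Pixel values.  Frames blanked by detector gating are held at 0.
    frame_rate : float
        Frames per second.
    pixel_size_um : float
        Micrometres per pixel (isotropic).
    frame_times : (T,) array
        Start time of each frame's exposure, seconds.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size_um: float
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def frame_centers(self) -> np.ndarray:
        """Mid-exposure time of each frame (s)."""
        return self.frame_times + 0.5 / self.frame_rate


@dataclass
class DaqTimeline:
    """Edge-list representation of the 20 kHz DAQ record.

    Dense 0/1 channel traces can be materialized with :meth:`channels`;
    the edge list is the canonical (and exactly serializable) form.
    """

    duration: float
    frame_times: np.ndarray
    led: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # on, off, level
    gating: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))  # on, off
    sensory: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))  # on, off
    rate: float = 20_000.0

    @property
    def led_onsets(self) -> np.ndarray:
        return self.led[:, 0] if len(self.led) else np.zeros(0)

    @property
    def led_levels(self) -> np.ndarray:
        return self.led[:, 2] if len(self.led) else np.zeros(0)

    @property
    def sensory_onsets(self) -> np.ndarray:
        return self.sensory[:, 0] if len(self.sensory) else np.zeros(0)

    def channels(self) -> dict[str, np.ndarray]:
        """Render dense 0/1 channel traces sampled at ``rate``."""
        n = int(round(self.duration * self.rate))
        t = np.arange(n) / self.rate
        out = {"time_s": t}
        for name, spans in (
            ("led", self.led[:, :2] if len(self.led) else np.zeros((0, 2))),
            ("gating", self.gating),
            ("sensory", self.sensory),
        ):
            ch = np.zeros(n, dtype=np.int8)
            for a, b in spans:
                ch[int(np.ceil(a * self.rate)) : int(np.ceil(b * self.rate))] = 1
            out[name] = ch
        sync = np.zeros(n, dtype=np.int8)
        idx = np.round(self.frame_times * self.rate).astype(int)
        sync[idx[idx < n]] = 1
        out["frame_sync"] = sync
        return out

    def gated_frames(self, frame_rate: float, pad_s: float = 0.0) -> np.ndarray:
        """Boolean mask of frames whose exposure overlaps a gating interval."""
        starts = self.frame_times
        stops = starts + 1.0 / frame_rate
        mask = np.zeros(len(starts), dtype=bool)
        for a, b in self.gating:
            mask |= (starts < b + pad_s) & (stops > a - pad_s)
        return mask


@dataclass
class GroundTruth:
    """Book-keeping of everything the simulator injected into a movie."""

    spike_times: list[np.ndarray]  # per cell, sorted (s); kernel-peak times
    voltage: np.ndarray  # (n_cells, T) -dF/F0 units on the frame grid
    gain: np.ndarray  # (n_cells,) mask-weighted fluorescence per unit (1 - v)
    background: float
    bleach_curve: np.ndarray  # (T,) multiplicative bleach factor
    gating_intervals: np.ndarray  # (n, 2) s
    parent_events: dict[int, np.ndarray] = field(default_factory=dict)
    led: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    sensory_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # IPSP ground truth, per cell
    ipsp_segment_amplitude: list[np.ndarray] = field(default_factory=list)  # (n_trig, n_seg)
    segment_edges_um: list[np.ndarray] = field(default_factory=list)
    segment_factors: list[np.ndarray] = field(default_factory=list)
    trial_factors: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cell_weights: list[np.ndarray] = field(default_factory=list)  # (H, W) per cell
    segment_label_maps: list[np.ndarray] = field(default_factory=list)  # (H, W) int, -1 off
    ipsp_gain: np.ndarray = field(default_factory=lambda: np.zeros(0))  # mask-weighted mean g

    def __post_init__(self) -> None:
        for st in self.spike_times:
            if np.any(np.diff(st) <= 0):
                raise ValueError("spike times must be strictly increasing")
        g = np.asarray(self.gating_intervals)
        if len(g) > 1:
            order = np.argsort(g[:, 0])
            if np.any(g[order][1:, 0] < g[order][:-1, 1]):
                raise ValueError("gating intervals must be non-overlapping")
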