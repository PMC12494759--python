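"""Temporally super-resolved triggered averages and per-trial response
features (IPSP amplitude and latencies, spike probability, per-segment
heterogeneity maps).

The imaging frame clock and the stimulation hardware are not synchronized,
so a trigger lands at a random phase within a frame.  Pooling every trial's
samples at their *true* latency (frame time minus trigger time, known to
DAQ precision) and re-binning onto a fine grid reconstructs the average
response far above the native frame rate.  Spike-triggered averages reach
sub-frame alignment through the per-spike Gaussian-fit offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traces import SpikeTrain

__all__ = [
    "TriggeredAverage",
    "upsampled_sta",
    "spike_triggered_average",
    "ResponseFeatures",
    "ipsp_features",
    "spike_probability",
    "SegmentResponseMap",
    "segment_response_map",
]


@dataclass
class TriggeredAverage:
    time_ms: np.ndarray  # upsampled grid, relative to trigger
    mean: np.ndarray
    sd: np.ndarray
    n: int  # accepted trials
    counts: np.ndarray  # samples per grid bin
    interpolated: np.ndarray  # True where the bin had no samples
    offsets_ms: np.ndarray  # per-trial sub-frame phase of the trigger
    dropped: list = field(default_factory=list)


def upsampled_sta(
    trace: np.ndarray,
    frame_times: np.ndarray,
    triggers: np.ndarray,
    window_ms: tuple[float, float] = (-50.0, 250.0),
    target_rate_hz: float = 2000.0,
) -> TriggeredAverage:
    """Trigger-aligned average, upsampled beyond the frame rate.

    Each trial's frame samples are placed at their true latency relative to
    the trigger; the pooled samples are binned onto the ``target_rate_hz``
    grid and averaged.  Bins without samples are linearly interpolated and
    flagged.  Trials whose window extends beyond the trace are dropped with
    a warning; NaN samples (gated frames) are excluded.
    """
    trace = np.asarray(trace, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    triggers = np.atleast_1d(np.asarray(triggers, dtype=float))
    if len(triggers) == 0:
        raise ValueError("need at least one trigger")
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError("window_ms must be increasing")
    step = 1000.0 / target_rate_hz
    grid = np.arange(0, int(np.floor((w1 - w0) / step + 1e-9)) + 1) * step + w0
    sums = np.zeros(len(grid))
    sqs = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    dt = frame_times[1] - frame_times[0] if len(frame_times) > 1 else 0.0
    offsets, dropped = [], []
    n_ok = 0
    for k, trig in enumerate(triggers):
        if trig + w0 / 1000.0 < frame_times[0] or trig + w1 / 1000.0 > frame_times[-1] + dt:
            dropped.append(k)
            continue
        lat = (frame_times - trig) * 1000.0
        sel = (lat >= w0 - step / 2) & (lat <= w1 + step / 2) & np.isfinite(trace)
        idx = np.round((lat[sel] - w0) / step).astype(int)
        ok = (idx >= 0) & (idx < len(grid))
        idx, vals = idx[ok], trace[sel][ok]
        np.add.at(sums, idx, vals)
        np.add.at(sqs, idx, vals**2)
        np.add.at(counts, idx, 1)
        offsets.append(float(((trig - frame_times[0]) % dt) * 1000.0) if dt else 0.0)
        n_ok += 1
    if dropped:
        warnings.warn(f"dropped {len(dropped)} trigger(s) whose window exceeds the trace")
    if n_ok == 0:
        raise ValueError("all triggers dropped: windows exceed the trace")
    mean = np.full(len(grid), np.nan)
    sd = np.zeros(len(grid))
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    multi = counts > 1
    var = np.zeros(len(grid))
    var[multi] = (sqs[multi] - sums[multi] ** 2 / counts[multi]) / (counts[multi] - 1)
    sd[multi] = np.sqrt(np.maximum(var[multi], 0.0))
    interpolated = ~nz
    if interpolated.any():
        good = np.flatnonzero(nz)
        mean[interpolated] = np.interp(np.flatnonzero(interpolated), good, mean[good])
    return TriggeredAverage(
        time_ms=grid,
        mean=mean,
        sd=sd,
        n=n_ok,
        counts=counts,
        interpolated=interpolated,
        offsets_ms=np.asarray(offsets),
        dropped=dropped,
    )


def spike_triggered_average(
    trace: np.ndarray,
    frame_times: np.ndarray,
    spikes: SpikeTrain,
    window_ms: tuple[float, float] = (-25.0, 50.0),
    target_rate_hz: float = 2000.0,
) -> TriggeredAverage:
    """Spike-triggered average aligned by the per-spike Gaussian-fit offset.

    Each detected spike's sub-frame offset shifts its alignment point before
    pooling; spikes whose Gaussian fit failed are aligned at their grid time.
    """
    if len(spikes) == 0:
        raise ValueError("empty spike train")
    offs = np.where(np.isfinite(spikes.offsets_ms), spikes.offsets_ms, 0.0)
    triggers = spikes.times + offs / 1000.0
    return upsampled_sta(trace, frame_times, triggers, window_ms, target_rate_hz)


@dataclass
class ResponseFeatures:
    """Per-trial IPSP read-out (amplitudes positive = hyperpolarization)."""

    amplitude: float  # -dF/F0 magnitude of the hyperpolarization
    time_to_peak_ms: float
    latency10_ms: float  # first crossing of 10% of the peak amplitude
    flagged: bool = False


def _ref_value(
    baseline: np.ndarray,
    frame_times: np.ndarray,
    trigger: float,
    ref_window_s: tuple[float, float] | None,
    missing: np.ndarray | None,
) -> float:
    """Pre-stimulus reference: mean over ``ref_window_s``, else the value at
    the trigger (linear interpolation)."""
    if ref_window_s is not None:
        ra = np.searchsorted(frame_times, trigger + ref_window_s[0], side="left")
        rb = np.searchsorted(frame_times, trigger + ref_window_s[1], side="right")
        ridx = np.arange(ra, rb)
        if missing is not None and len(ridx):
            ridx = ridx[~np.asarray(missing, dtype=bool)[ridx]]
        if len(ridx):
            return float(baseline[ridx].mean())
    j = np.clip(np.searchsorted(frame_times, trigger), 1, len(frame_times) - 1)
    t0, t1 = frame_times[j - 1], frame_times[j]
    frac = 0.0 if t1 == t0 else (trigger - t0) / (t1 - t0)
    return float((1 - frac) * baseline[j - 1] + frac * baseline[j])


def ipsp_features(
    baseline: np.ndarray,
    frame_times: np.ndarray,
    trigger: float,
    search_window_s: tuple[float, float] = (0.02, 0.2),
    missing: np.ndarray | None = None,
    ref_window_s: tuple[float, float] | None = (-0.2, -0.05),
) -> ResponseFeatures:
    """Extract IPSP amplitude/latency from the low-pass baseline signal.

    Amplitude is the pre-stimulus reference minus the minimum of the
    baseline in the post-stimulus search window (20-200 ms); gated samples
    are excluded from the minimum search.  The reference is the mean of the
    baseline over ``ref_window_s`` before the trigger: the zero-phase
    baseline filter spreads the response symmetrically in time, so the
    baseline *at* the trigger already contains part of the response; a
    window ending 50 ms before the stimulus is outside that spread yet
    close enough to be drift-immune.  (``ref_window_s=None`` reads the
    baseline at the trigger instead.)  Time-to-peak is the latency of the
    minimum; latency-to-10% is the first crossing of 10% of the amplitude
    after the stimulus.
    """
    baseline = np.asarray(baseline, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    ref = _ref_value(baseline, frame_times, trigger, ref_window_s, missing)
    a = np.searchsorted(frame_times, trigger + search_window_s[0], side="left")
    b = np.searchsorted(frame_times, trigger + search_window_s[1], side="right")
    idx = np.arange(a, b)
    if missing is not None and len(idx):
        idx = idx[~np.asarray(missing, dtype=bool)[idx]]
    if len(idx) == 0:
        return ResponseFeatures(np.nan, np.nan, np.nan, flagged=True)
    i_min = idx[np.argmin(baseline[idx])]
    amplitude = ref - float(baseline[i_min])
    t_peak = (frame_times[i_min] - trigger) * 1000.0
    if amplitude <= 0:
        return ResponseFeatures(amplitude, t_peak, np.nan, flagged=True)
    thresh = ref - 0.1 * amplitude
    start = np.searchsorted(frame_times, trigger, side="right")
    lat10 = np.nan
    for i in range(start, i_min + 1):
        if missing is not None and missing[i]:
            continue
        if baseline[i] <= thresh:
            lat10 = (frame_times[i] - trigger) * 1000.0
            break
    return ResponseFeatures(amplitude, t_peak, lat10, flagged=False)


def spike_probability(
    spike_times: np.ndarray, triggers: np.ndarray, window_s: float = 0.15
) -> float:
    """``P(spike | stimulus)``: fraction of triggers followed by >= 1 spike
    within ``window_s``."""
    spike_times = np.asarray(spike_times, dtype=float)
    triggers = np.sort(np.atleast_1d(np.asarray(triggers, dtype=float)))
    if len(triggers) == 0:
        raise ValueError("need at least one trigger")
    if len(triggers) > 1 and np.any(np.diff(triggers) < window_s):
        raise ValueError("trigger windows overlap")
    hits = 0
    for t in triggers:
        if np.any((spike_times > t) & (spike_times <= t + window_s)):
            hits += 1
    return hits / len(triggers)


@dataclass
class SegmentResponseMap:
    """Per-segment response features and their coefficient of variation."""

    per_segment: np.ndarray  # trial-mean feature per segment
    per_trial: np.ndarray | None  # (n_segments, n_trials) or None
    cv: float  # sd / |mean| across segments (NaN if mean == 0, flagged)
    flagged: bool


def segment_response_map(
    segment_baselines: np.ndarray,
    frame_times: np.ndarray,
    triggers: np.ndarray | None = None,
    spikes: SpikeTrain | None = None,
    feature: str = "ipsp",
    segment_dff: np.ndarray | None = None,
    search_window_s: tuple[float, float] = (0.02, 0.2),
    missing: np.ndarray | None = None,
) -> SegmentResponseMap:
    """Map a response feature along the dendrite and quantify heterogeneity.

    ``feature='ipsp'``: the IPSP trough latency is estimated once per cell
    from the trial-averaged, segment-averaged baseline response; every
    segment and trial is then read out at that single fixed latency (minus
    its own pre-stimulus reference).  A fixed common read-out time is
    essential for the heterogeneity map: a per-trial or per-segment minimum
    search selects on noise, which adds a common offset and flattens the
    across-segment contrast, breaking the plain variance decomposition of
    the CV.
    ``feature='cs_amplitude'``: the segment's unfiltered -dF/F0 read at the
    spike times detected on the whole-cell trace (a common event set for
    all segments).  CV is the across-segment sample SD over |mean|.
    """
    seg_base = np.atleast_2d(np.asarray(segment_baselines, dtype=float))
    n_seg = seg_base.shape[0]
    if n_seg < 2:
        raise ValueError("need at least 2 segments")
    frame_times = np.asarray(frame_times, dtype=float)
    if feature == "ipsp":
        if triggers is None or len(np.atleast_1d(triggers)) == 0:
            raise ValueError("ipsp feature needs triggers")
        triggers = np.atleast_1d(np.asarray(triggers, dtype=float))
        mean_base = seg_base.mean(axis=0)
        dt = frame_times[1] - frame_times[0] if len(frame_times) > 1 else 1.0
        off_lo = int(np.ceil(search_window_s[0] / dt))
        off_hi = int(np.floor(search_window_s[1] / dt))
        offsets = np.arange(off_lo, off_hi + 1)
        # trial-averaged response of the segment-mean baseline
        starts = np.searchsorted(frame_times, triggers)
        ok_trials = (starts + off_hi < len(frame_times)) & (starts + off_lo >= 0)
        if not ok_trials.any():
            raise ValueError("no trigger has a full search window inside the trace")
        rows = starts[ok_trials][:, None] + offsets[None, :]
        resp = mean_base[rows].astype(float)
        if missing is not None:
            resp[np.asarray(missing, dtype=bool)[rows]] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            avg = np.nanmean(resp, axis=0)
        trough_off = offsets[int(np.nanargmin(avg))]
        per_trial = np.full((n_seg, len(triggers)), np.nan)
        for j, trig in enumerate(triggers):
            if not ok_trials[j]:
                continue
            i_tr = starts[j] + trough_off
            if missing is not None and missing[i_tr]:
                continue
            for s in range(n_seg):
                ref = _ref_value(seg_base[s], frame_times, trig, (-0.2, -0.05), missing)
                per_trial[s, j] = ref - seg_base[s][i_tr]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_segment = np.nanmean(per_trial, axis=1)
    elif feature == "cs_amplitude":
        if spikes is None or len(spikes) == 0:
            raise ValueError("cs_amplitude feature needs a detected spike train")
        if segment_dff is None:
            raise ValueError("cs_amplitude feature needs segment_dff traces")
        seg_dff = np.atleast_2d(np.asarray(segment_dff, dtype=float))
        per_trial = seg_dff[:, spikes.indices]
        per_segment = per_trial.mean(axis=1)
    else:
        raise ValueError(f"unknown feature: {feature}")
    mu = float(np.mean(per_segment))
    if mu == 0 or not np.isfinite(mu):
        return SegmentResponseMap(per_segment, per_trial, float("nan"), flagged=True)
    cv = float(np.std(per_segment, ddof=1) / abs(mu))
    return SegmentResponseMap(per_segment, per_trial, cv, flagged=False)
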