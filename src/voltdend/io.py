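"""File interchange: multi-page TIFF movies, DAQ edge lists, CSV tables.

Only auditable text/standard formats are used: TIFF for movies and masks,
CSV for traces and event tables, JSON for configurations, edge lists and
ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .data import DaqTimeline, Movie
from .traces import SpikeTrain

__all__ = [
    "write_movie",
    "read_movie",
    "write_daq_json",
    "read_daq_json",
    "write_daq_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_spikes_csv",
    "read_spikes_csv",
]


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a frame-major multi-page TIFF with geometry metadata."""
    meta = {
        "frame_rate": movie.frame_rate,
        "pixel_size_um": movie.pixel_size_um,
        "t0": float(movie.frame_times[0]),
    }
    tifffile.imwrite(str(path), movie.data, metadata=meta)


def read_movie(path: str | Path) -> Movie:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    frame_rate = float(meta.get("frame_rate", 440.0))
    t0 = float(meta.get("t0", 0.0))
    return Movie(
        data=data.astype(np.float32),
        frame_rate=frame_rate,
        pixel_size_um=float(meta.get("pixel_size_um", 0.8)),
        frame_times=t0 + np.arange(data.shape[0]) / frame_rate,
    )


def write_daq_json(path: str | Path, daq: DaqTimeline) -> None:
    """Compact edge-list serialization of the DAQ timeline."""
    payload = {
        "rate": daq.rate,
        "duration": daq.duration,
        "frame_times": daq.frame_times.tolist(),
        "led": daq.led.tolist(),
        "gating": daq.gating.tolist(),
        "sensory": daq.sensory.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_daq_json(path: str | Path) -> DaqTimeline:
    d = json.loads(Path(path).read_text())
    return DaqTimeline(
        duration=float(d["duration"]),
        frame_times=np.asarray(d["frame_times"], dtype=float),
        led=np.asarray(d["led"], dtype=float).reshape(-1, 3),
        gating=np.asarray(d["gating"], dtype=float).reshape(-1, 2),
        sensory=np.asarray(d["sensory"], dtype=float).reshape(-1, 2),
        rate=float(d.get("rate", 20000.0)),
    )


def write_daq_csv(path: str | Path, daq: DaqTimeline) -> None:
    """Dense 0/1 channel levels at the DAQ rate (large; edge JSON preferred)."""
    pd.DataFrame(daq.channels()).to_csv(path, index=False)


def write_trace_csv(path: str | Path, time_s: np.ndarray, value: np.ndarray, name: str = "value") -> None:
    pd.DataFrame({"time_s": time_s, name: value}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_spikes_csv(path: str | Path, spikes: SpikeTrain) -> None:
    pd.DataFrame(
        {
            "time_s": spikes.times,
            "amplitude": spikes.amplitudes,
            "baseline": spikes.baselines,
            "offset_ms": spikes.offsets_ms,
            "width_ms": spikes.widths_ms,
            "confidence": spikes.confident.astype(int),
        }
    ).to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> SpikeTrain:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    return SpikeTrain(
        times=t,
        indices=np.zeros(len(t), dtype=int),
        amplitudes=df["amplitude"].to_numpy(float),
        baselines=df["baseline"].to_numpy(float),
        offsets_ms=df["offset_ms"].to_numpy(float),
        widths_ms=df["width_ms"].to_numpy(float),
        confident=df["confidence"].to_numpy(bool),
    )
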