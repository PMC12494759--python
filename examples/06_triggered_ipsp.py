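"""Optogenetically evoked IPSPs: temporally super-resolved triggered average
and graded amplitude extraction across LED intensities."""

import numpy as np

from voltdend.pipeline import analyze_fov
from voltdend.synth import SceneConfig, simulate_movie
from voltdend.traces import DffTrace
from voltdend.triggered import ipsp_features, upsampled_sta

config = SceneConfig(
    n_cells=1, field_shape=(14, 48), duration_s=122.0, led_enabled=True,
    led_levels=[0.5, 1.0, 1.5], seed=11,
)
movie, daq, truth = simulate_movie(config)
weights = truth.cell_weights[0].ravel()
raw = movie.data.reshape(movie.n_frames, -1) @ (weights / weights.sum())
trace = DffTrace.from_raw(raw, config.frame_rate, gating_intervals=daq.gating)

print(f"{len(daq.led_onsets)} LED pulses, levels cycling {config.led_levels}")
for level in (0.5, 1.0, 1.5):
    sel = daq.led_levels == level
    sta = upsampled_sta(trace.baseline, trace.time_s, daq.led_onsets[sel],
                        window_ms=(-280, 400), target_rate_hz=config.frame_rate)
    f = ipsp_features(sta.mean, sta.time_ms / 1000, trigger=0.0)
    print(f"  level {level:3.1f}: amplitude {f.amplitude:.4f} -dF/F0, "
          f"time-to-peak {f.time_to_peak_ms:.0f} ms, latency-to-10% {f.latency10_ms:.0f} ms")
print("Amplitudes scale with LED intensity; the ~0.079 base amplitude and the")
print("~85 ms time-to-peak reflect the generator's feed-forward IPSP kernel")
print("(latencies read on the 4 Hz-filtered baseline are smoothed upward).")

# dendritic heterogeneity of the same responses
results = analyze_fov(movie, daq, truth.cell_weights)
print(f"per-segment IPSP map CV = {results[0].cv:.3f}")
print("A positive CV reflects the programmed dendritic heterogeneity (cv = 0.13),")
print("damped in any single session by segment-boundary mixing and finite trials.")
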