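"""Detect complex spikes on a simulated dendrite and score detectability.

Runs the two-pass detector (-dF/F0, zero-phase 4 Hz baseline, 3 sigma
threshold on the one-frame-smoothed residual, spike excision and re-
estimation) and reports sensitivity against ground truth plus the
discriminability index d'.
"""

import numpy as np

from voltdend.synth import SceneConfig, calibrate_noise_for_dprime, simulate_movie
from voltdend.traces import DffTrace, discriminability

base = SceneConfig(n_cells=1, field_shape=(16, 64), duration_s=60.0)
noise = calibrate_noise_for_dprime(base, target_dprime=5.0)
config = base.model_copy(update={"noise_scale": noise, "seed": 7})
movie, daq, truth = simulate_movie(config)

weights = truth.cell_weights[0].ravel()
raw = movie.data.reshape(movie.n_frames, -1) @ (weights / weights.sum())
trace = DffTrace.from_raw(raw, config.frame_rate)
spikes = trace.detect()

true_times = truth.spike_times[0]
hits = [np.min(np.abs(spikes.times - t)) <= 1.5 / config.frame_rate for t in true_times]
d = discriminability(trace.values, spikes, config.frame_rate, seed=7)

print(f"true spikes: {len(true_times)}, detected: {len(spikes)}")
print(f"sensitivity: {100 * np.mean(hits):.1f}%  (movie calibrated to d' ~ 5)")
print(f"measured d' = {d.d_prime:.2f}  (mu_S={d.mu_s:.3f}, sigma_B={d.sigma_b:.3f})")
print(f"median spike amplitude: {np.median(spikes.amplitudes):.3f} -dF/F0")
print("Amplitudes near 0.25-0.31 are the 440 Hz frame-sampled complex-spike peak.")
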