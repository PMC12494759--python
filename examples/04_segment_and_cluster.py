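"""Refine dendrite masks, cut 4.8 um segments, and cluster segments into
cells by spike-band correlation."""

import numpy as np

from voltdend.segmentation import (
    cluster_segments,
    extract_traces,
    fit_dendrite_path,
    refine_mask,
    segment_path,
)
from voltdend.synth import SceneConfig, simulate_movie

config = SceneConfig(n_cells=2, field_shape=(20, 64), duration_s=60.0, seed=3)
movie, daq, truth = simulate_movie(config)

traces, owner = [], []
for cell, mask in enumerate(truth.cell_weights):
    refined = refine_mask(mask, sigma=1.0)            # N(G(X))^3
    path = fit_dendrite_path(refined, config.pixel_size_um)
    segset = segment_path(path, refined, segment_length_um=4.8)
    print(f"cell {cell}: path arc length {path.arc_length_um:.1f} um "
          f"-> {segset.n_segments} segments of ~4.8 um")
    traces.append(extract_traces(movie, segset))
    owner.extend([cell] * segset.n_segments)

clusters, excluded = cluster_segments(np.vstack(traces), config.frame_rate, threshold_r=0.5)
owner = np.asarray(owner)
print(f"clustering found {len(clusters)} cells (truth: 2)")
for k, cl in enumerate(clusters):
    src = set(owner[cl.segment_ids].tolist())
    iu = np.triu_indices(len(cl.segment_ids), 1)
    print(f"  cluster {k}: {len(cl.segment_ids)} segments, all from true cell(s) {src}, "
          f"mean within-cluster r = {cl.corr[iu].mean():.2f}")
print("Two pure clusters with high within-cluster r show that shared complex")
print("spikes, not shared bleaching, drive the grouping.")
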