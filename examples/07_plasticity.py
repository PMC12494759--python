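"""Pre/post plasticity comparison on a reduced simulated experiment:
programmed +25% IPSP potentiation vs an unchanged control, matched across
sessions, tested with the paired Wilcoxon and the animal/FOV mixed model.

The full-size experiment (32 cells per group) is what
``scripts/acceptance.py`` runs; this example uses 8 cells per group to
finish in ~30 s.
"""

import warnings

import numpy as np

from voltdend.pipeline import simulate_plasticity_experiment

warnings.filterwarnings("ignore")

out = simulate_plasticity_experiment(
    seed=4, n_cells_per_group=8, mice_per_group={"pairing": 2, "control": 2}
)

for group, comp in out["comparisons"].items():
    print(f"{group}: n = {comp.n} matched cells, "
          f"median log ratio = {np.median(comp.log_ratios):+.3f}, "
          f"paired Wilcoxon p = {comp.p_value:.2g}")
gd = out["group_difference"]
print(f"mixed model (animal + FOV random effects): "
      f"group effect = {gd.estimate:+.3f}, Wald-t p = {gd.p_value:.2g} [{gd.method}]")
print(f"A pairing median log ratio near ln(1.25) = {np.log(1.25):.3f} and a")
print("control near 0 mean the pipeline recovers the programmed potentiation")
print("through simulation, segmentation, matching and feature extraction.")
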