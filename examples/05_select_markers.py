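"""Rank features by ReliefF and report per-marker diagnostics.

Runs exhaustive ReliefF (k = 10 neighbours) on the log-intensity matrix
and prints the top markers with their sensitivity/specificity/PPV/NPV at
the Youden-optimal threshold of each feature's own ROC curve.
"""

import numpy as np

from mdinet import SimulationConfig, generate_cohort, generate_metabolome
from mdinet.select import build_marker_set, log2_halfmin

cfg = SimulationConfig(seed=4, n_metabolites=250, n_differential=20,
                       effect_size=2.0)
gt = generate_metabolome(cfg)
cohort = generate_cohort(gt, cfg)

rng = np.random.default_rng(4)
inten = np.exp2(cohort.true_log_intensity.to_numpy().T)
inten[rng.random(inten.shape) < cfg.dropout] = 0.0     # detection dropout
X = log2_halfmin(inten)
y = cohort.metadata["group"].to_numpy()
ids = [f"F{i}" for i in range(gt.n)]

markers = build_marker_set(X, y, ids, gt.ion_masses, n_select=20,
                           k_neighbors=10, seed=4)
cols = ["weight", "direction", "sens", "spec", "ppv", "npv", "auc"]
print(markers.table[cols].head(8).round(3))
planted = {f"F{i}" for i in gt.differential}
print(f"\nplanted markers recovered: "
      f"{len(planted & set(markers.feature_ids))}/{len(planted)}")
# ReliefF weights reward features whose nearest other-class neighbours
# differ more than same-class ones — it sees interactions, not just means.
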