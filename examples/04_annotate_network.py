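"""Build the mass-difference network and propagate molecular formulas.

Connects neutralised feature masses whose differences match catalogue
building blocks, then spreads formulas outward from a 5% subset of known
seed annotations; every accepted assignment must agree with its feature
mass within the ppm tolerance.
"""

import numpy as np

from mdinet import (SimulationConfig, build_network, check_assignments,
                    default_building_blocks, generate_metabolome,
                    propagate_formulas)

cfg = SimulationConfig(seed=3, n_metabolites=300, n_differential=20)
gt = generate_metabolome(cfg)
order = np.argsort(gt.neutral_masses)
masses = gt.neutral_masses[order]
ids = [f"F{i}" for i in range(gt.n)]

net = build_network(ids, masses, default_building_blocks(), tol_ppm=1.0)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges")

rng = np.random.default_rng(0)
seed_pos = rng.choice(gt.n, size=gt.n // 20, replace=False)
seeds = {ids[np.searchsorted(masses, gt.neutral_masses[k])]: gt.formulas[k]
         for k in seed_pos}
assigns = propagate_formulas(net, seeds, tol_ppm=1.0)
truth = {ids[i]: gt.formulas[order[i]] for i in range(gt.n)}
correct = sum(a.assigned and a.formula == truth[a.feature_id] for a in assigns)
print(f"seeds: {len(seeds)}  assigned: {sum(a.assigned for a in assigns)}  "
      f"correct: {correct}/{gt.n}")
print(check_assignments(assigns, dict(zip(ids, masses)), net).to_string(index=False))
# A handful of known compounds suffices to annotate the whole connected
# metabolome, because each edge fixes the elemental difference exactly.
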