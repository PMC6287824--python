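"""Covariate-adjusted group contrasts (ANCOVA with LS-means).

Shows why adjustment matters: a feature driven purely by age looks
group-different to a naive t-test in an age-unmatched cohort, while the
LS-mean contrast at mean age and a 50/50 sex mix stays calibrated.
"""

import numpy as np
from scipy import stats

from mdinet import SimulationConfig, generate_cohort, generate_metabolome
from mdinet.glm import fit_ancova

cfg = SimulationConfig(seed=6, n_metabolites=30, n_differential=0)
gt = generate_metabolome(cfg)
cohort = generate_cohort(gt, cfg)
meta = cohort.metadata
rng = np.random.default_rng(6)

age_driven = 0.05 * meta.age.to_numpy() + rng.normal(0, 1, len(meta))
t = stats.ttest_ind(age_driven[meta.group == "case"],
                    age_driven[meta.group == "control"])
r = fit_ancova(age_driven, meta.group, meta.age, meta.sex)
print(f"age-driven feature:  naive t-test p = {t.pvalue:.4f}   "
      f"adjusted contrast p = {r.p_value:.4f}")
print(f"LS-means  case {r.lsmean_case:.3f}  control {r.lsmean_control:.3f}  "
      f"({r.direction})")
print(f"interaction screens: group x age p = {r.p_gxage:.3f}, "
      f"group x sex p = {r.p_gxsex:.3f}")
# The naive test mistakes the cohorts' 20-year age gap for a disease
# effect; the adjusted contrast does not.
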