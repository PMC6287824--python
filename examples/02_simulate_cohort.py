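"""Generate a synthetic case/control metabolomics cohort.

Builds a 300-metabolite ground-truth metabolome connected by
building-block mass differences, draws the default 31-case / 95-control
cohort with unmatched age and sex, and renders per-sample peak lists with
mass-error curves, 13C satellites, noise peaks and dropout.
"""

from mdinet import SimulationConfig, simulate_dataset

cfg = SimulationConfig(seed=1, n_metabolites=300, n_differential=20)
gt, cohort, peaks = simulate_dataset(cfg)

print(cohort.metadata.groupby("group").agg(
    n=("age", "size"), mean_age=("age", "mean")).round(1))
print(f"\nmetabolites: {gt.n}  (differential: {len(gt.differential)}, "
      f"log2 effects {gt.effects.min():+.1f}..{gt.effects.max():+.1f})")
n_peaks = [len(p) for p in peaks.values()]
print(f"peaks per sample: {min(n_peaks)}-{max(n_peaks)} "
      f"(metabolites + satellites + noise, after dropout)")
# The age gap between groups is deliberate: it gives the covariate-adjusted
# models real confounding to remove, as in an unmatched clinical cohort.
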