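# Methods

This note documents the models and procedures implemented in `mdinet`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data tests do and do not demonstrate.

## Exact-mass arithmetic

Atomic masses are pinned in code (Da): C = 12 exactly, H = 1.007825032,
N = 14.003074005, O = 15.994914620, P = 30.973761998, S = 31.972071174,
electron = 0.000548580. Negative-mode electrospray produces [M−H]⁻ ions,
so ion mass = neutral mass − m(H) + m(e⁻); the neutral/ion difference is
one proton, 1.0072765 Da. Published reference tables round atomic masses
differently; the worked-example checks therefore use a ±0.001 Da band,
which absorbs the ≤ 2.4 × 10⁻⁴ Da drift observed against the reference
compound list while still rejecting any wrong formula (the smallest
CHNOPS near-degeneracy at these masses is far larger). The element scope
defaults to CHNOPS; other symbols parse if given an atomic mass.

The building-block catalogue (CH₂, H₂, O, H₂O, CO, CO₂, NH₃, NH, CH₂O,
C₂H₂O, C₂H₄, S, SO₃, HPO₃) ships as a package TSV and in code; users
supply their own TSV (`label`, `formula`, optional `description`) to
extend or replace it. Blocks are unsigned — the direction of a mass
difference is a property of the network edge, not the block — and labels
must be unique.

## Synthetic cohorts

The generator emulates a case/control cerebrospinal-fluid profiling
design at desk scale.

* **Metabolome.** Formulas are grown by chaining: each new metabolite is
  an existing one plus a random building block, accepted if the neutral
  mass stays in 123–1000 Da and the elemental ratios are plausible
  (0.2 ≤ H/C ≤ 3, O/C ≤ 1.2). Chaining guarantees every metabolite has a
  catalogue neighbour, so the ground-truth network is connected — the
  property formula propagation needs. Differential features are attached
  to the backbone with block choice tilted toward the configured
  enriched blocks (multiplier 3 by default), and each receives
  ⌈multiplier⌉ − 1 "companion" neighbours through an enriched block: this
  is the planted signal MDEA is meant to recover.
* **Cohort.** 31 cases / 95 controls; ages truncated-normal
  (65.5 ± 12.2 vs 44.9 ± 17.3 y, floor 18); sex counts fixed at 9f/22m
  and 59f/36m. The imbalance is deliberate: the ANCOVA stage needs real
  confounding to adjust for. Intensities are log2-normal — base level per
  metabolite N(17, 1.5²), per-sample spread N(0, 1) — with the group
  effect (default ±2 log2 units, two-thirds of markers up) added to
  cases. No distributional family is claimed for real data; log-normal is
  the conventional choice for spectral intensities.
* **Peak rendering.** Observed m/z = ion mass × (1 + e_s(m)·10⁻⁶) +
  N(0, σ·m·10⁻⁶) with a per-sample linear error curve e_s (coefficients
  N(0, 0.2 ppm)) and jitter σ = 0.05 ppm; features drop out independently
  (p = 0.10, "absent = zero"); surviving features spawn a ¹³C satellite
  with probability 0.5 at +1.0033548 Da and intensity 1.1 % per carbon;
  100 uniform noise peaks per sample. Raw profile spectra, adducts other
  than [M−H]⁻, isotope fine structure and medication subgroups are not
  simulated.

What passing tests show: the algorithms recover exactly the structure the
generator plants. What they do not show: robustness to correlated
metabolite intensities, batch effects, retention-time artefacts (none in
direct infusion), ion suppression, or real annotation ambiguity — real
spectra are harsher in all these respects.

## Recalibration

The error curve is estimated from candidate matches between observed
peaks and reference masses within a 3 ppm window. Matches populate a 2-D
histogram (50 m/z bins × 0.05 ppm bins); per m/z bin the modal ppm cell,
refined by the mean of matches in that cell ± 1 neighbour, yields a ridge
point weighted by density. A density-weighted quadratic is fitted to the
ridge with one re-weighting pass that zeroes > 3σ outliers; predictions
are clipped to ±5 ppm. With fewer than 20 matches the curve falls back to
identity and is flagged. On simulated linear drifts the fit is accurate
to ~0.03 ppm, comfortably inside the 0.1 ppm design target.

Because no public reference list exists for arbitrary samples, the
pipeline self-calibrates: a first uncalibrated alignment provides
consensus m/z of features present in ≥ 70 % of samples, and each sample
is recalibrated against those. This removes per-sample *relative* error
(what alignment needs); a common absolute offset would survive, which is
why external single-point calibration exists upstream on real
instruments and is represented in the simulator only.

## Alignment and filtering

Pooled peaks are sorted by m/z and cut into clusters wherever the gap to
the previous peak exceeds tol × m (tol = 1 ppm). This gap rule bounds the
cluster span only indirectly (≤ 2 tol in practice at these densities) but
makes alignment order-independent and deterministic; fixed-grid binning
was rejected because bin edges split genuine features. If one sample
contributes several peaks to a cluster, its most intense peak wins.
Consensus m/z is the intensity-weighted mean. Feature frequency is
computed after alignment and before annotation; the default 10 % cutoff
removes one-off chemical noise while keeping anything reproducibly
detected (at n = 126: present in 13 samples survives, 12 does not).

## Network annotation

Edges are found per block by a two-pointer sweep over the sorted neutral
masses; an edge (i, j, block) requires |(m_j − m_i) − Δm| ≤ tol·m_j·10⁻⁶.
Formula propagation is a deterministic breadth-first fixpoint rather than
literal random walks: reproducibility was preferred over stochastic
exploration, and the fixpoint visits everything a walk could. Candidates
(neighbour formula ± edge delta) must have non-negative element counts
and match the node mass within tolerance. When several candidates reach
a node, the one whose ppm error is closest to the current median network
error wins — this operationalises consistency with the spectrum's
intrinsic error distribution — with ties broken by |error|, then by
formula string, making the result independent of visit order. A post-pass
re-validates every assignment independently and reports the fraction of
edges between assigned nodes whose formula difference contradicts the
edge label.

Isotopologue flagging precedes annotation: a feature is a ¹³C satellite
if it sits +1.0033548 Da (within tolerance) above a feature whose median
intensity makes the heavy/light ratio < 0.6. The ratio guard keeps
genuine metabolites one mass unit apart (the ratio for a real ¹³C
satellite is ~0.011 × #C ≤ ~0.5 for CHNOPS metabolites below 1000 Da).
"Noise" is defined as degree-zero and unassigned. Compound names come
from a small packaged offline table (formula → names); it covers the
reference compounds and common metabolites only and applies no filtering.

## Marker selection

ReliefF: features are scaled to [0, 1] by range (making weights invariant
to per-feature affine rescaling); for each instance the k = 10 nearest
hits and misses (Euclidean distance on scaled features) update the
weights, miss contributions weighted by class priors; iteration is
exhaustive over all instances by default and deterministic. Classes must
exceed k members. Ties in the final ranking break toward the smaller
m/z. Because zero intensities are detection dropouts, the modelling
matrix uses half-minimum imputation on the log2 scale
(`log2_halfmin`) before ReliefF and the latent models; without it,
dropout noise dominates the scaled distances. The stored feature matrix
keeps its zeros.

Per-marker diagnostics use the Youden-optimal threshold (max sens + spec
− 1) of the feature's own empirical ROC, with the direction of change
(up/down in cases) auto-detected from the median difference; no single
published thresholding rule exists for such tables, so the Youden rule is
stated explicitly. Constant features return chance-level diagnostics
flagged `degenerate`.

## Latent-variable classification

sPLS-DA: NIPALS on the dummy-coded class matrix with autoscaled X
(unit-variance scaling is the default; the choice is configurable only by
pre-scaling). Per component, the X-weight vector is soft-thresholded so
exactly keepX entries stay nonzero; keepX = p reproduces dense PLS-DA to
machine precision. Deflation is standard (X and Y by the score
regression); the stored residual reconstructs X exactly. Projection uses
w* = W(P′W)⁻¹, whose leading columns coincide with truncated models, so
BER can be reported per component count from one fit.

OPLS-DA: per orthogonal round, the weight w ∝ X′y is recomputed from the
current X, the loading's y-orthogonal part is split off, and its
component removed; orthogonal scores are uncorrelated with y exactly in
training. One predictive component follows. With zero orthogonal
components the predictive scores equal dense PLS's first component.

Cross-validation is stratified 7-fold, fold assignment a function of
(seed, y) only. Q² = 1 − PRESS/SS on held-out dummy responses; R²Y on
the full fit; class prediction by the largest predicted dummy column
(max-distance rule); BER is the mean per-class error; ROC/AUC from
held-out first-component scores oriented per training fold. Model
significance is a permutation test: the true Q² is ranked among Q² values
from label-permuted reruns (default 100–200). This replaces parametric
cross-validation ANOVA, which is tied to a proprietary implementation; it
is a substitute with the same null, not a reimplementation.

## Covariate adjustment

Each feature gets two OLS fits: an interaction screen
(`y ~ group + age + sex + group:age + group:sex`) whose interaction
p-values are reported and flagged at α = 0.05, and a main-effects model
from which LS-means are evaluated at the cohort mean age and a 50/50 sex
mix. With this parametrisation the LS-mean contrast equals the group
coefficient and its t-test; with exactly two groups the Dunnett
many-to-one adjustment is the identity, so the contrast p is reported
unadjusted (computed as such, not approximated). Constant covariates are
dropped from the design with a record in the result, which also makes the
no-covariate case collapse exactly to the pooled t-test. No multiplicity
correction is applied across features by default (a Benjamini–Hochberg
switch exists on the interaction screen).

## MDEA

For each block, edges are cross-classified as (carries block) ×
(touches ≥ 1 marker node); "touches" can be switched to
exactly-one-endpoint (`touch_rule="one"`) to count only marker↔background
edges — the default counts marker–marker edges too, treating the whole
marker neighbourhood as signal. The one-sided enrichment p is the
hypergeometric tail with margins fixed, and Z = (a − E a)/√Var a from the
hypergeometric moments rather than inverted from p, so the Z ≈ 2 ↔
p ≈ 0.05 correspondence holds in the large-sample limit by construction.
Degenerate margins (every edge the same block, or all/none touching)
yield Z = 0, p = 1; blocks with no edges are still reported. Fisher's
exact test is conservative on discrete tables, so the false-enrichment
rate under random marker sets sits at or slightly below the nominal 5 %.

## Problem sizes and numerical choices

Simulation-backed tests run at 150–400 metabolites and the full
126-sample cohort — large enough that alignment, propagation and
selection face thousands of peaks, small enough for a laptop-scale test
suite; the Monte-Carlo stages use 50 seeds (recovery rates) and 250
replicates (type-I error). Alignment and network construction are
O(n log n)-ish sweeps and handle 10⁴-feature spectra directly. Tolerances
throughout default to the 1 ppm window; calibration bins (50 × 0.05 ppm),
the 0.6 isotopologue ratio, the 70 % self-calibration frequency, k = 10
ReliefF neighbours and 7 CV folds are configuration defaults, each
exposed in the corresponding config object. All randomness flows through
explicit integer seeds; reruns of the pipeline with the same config are
byte-identical (SVG output included, via a fixed hash salt).

## Known limitations

* Formula propagation is only as good as the network's connectivity and
  the seed set; disconnected components without seeds stay unassigned.
* The 2 × 2 MDEA table treats edges as exchangeable; correlated edges
  (hub nodes) violate the hypergeometric null slightly.
* Q² ≤ R²Y is observed on all tested configurations but is not a
  mathematical identity for held-out data.
* The self-calibration scheme cannot recover a global absolute mass
  offset common to all samples.
* The offline name table is a convenience lookup, not an annotation
  engine; it makes no claim of uniqueness or coverage.
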