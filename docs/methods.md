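# Methods

`paddyopt` models the input–benefit system of four rice planting methods used
in Southwest China — mechanical transplanting (MT), mechanical direct seeding
(MD), manual transplanting (MAT) and manual direct seeding (MAD) — and
searches for fertilizer/seed adjustments that improve a method's benefits.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic cohorts do and do not establish.

## Benefit accounting

Every field-season record carries per-hectare inputs (N, P₂O₅, K₂O and seed in
kg/ha; herbicide and pesticide in kg/ha; labor and machinery in h/ha) and a
grain yield. Five indicators are computed per record from a coefficient table
of unit costs (CNY), emission factors (kg CO₂-eq) and energy equivalents (MJ):

* **Economic benefit (EB)** = grain yield × sale price − Σ(input × unit cost),
  CNY/ha. Labor is priced per hectare-season (the source table prices it per
  ha while machinery is per hour); machinery cost is hours × CNY/h.
* **GHG emissions** = Σᵢ Rᵢ·Dᵢ over all inputs, kg CO₂-eq/ha, where Rᵢ is the
  amount and Dᵢ the emission factor. The scope is input-embodied emissions
  only; field CH₄/N₂O fluxes are not modelled.
* **Partial fertilizer productivity (PFP)** = grain yield / (N + P₂O₅ + K₂O).
  Seed mass is *not* fertilizer and is excluded from the denominator.
* **Energy use efficiency (EUE)** = output energy / input energy, with output
  = grain × 14.7 MJ/kg + straw × 12.5 MJ/kg. Straw yield is rarely reported;
  when missing it is imputed as straw = grain (harvest index 0.5) for the
  output side only, configurable via `straw_to_grain_ratio`.

Zero total fertilizer or zero input energy make PFP/EUE undefined; these are
carried as missing values (never zeros) and excluded from pooled means, so
they cannot corrupt banding thresholds.

The default coefficient table ships in
`src/paddyopt/data/default_coefficients.yaml`. The seed row (5 CNY/kg, 0 kg
CO₂-eq/kg, 17 MJ/kg) and the labor rows (1500 CNY/ha-season, 0 kg CO₂-eq/h,
14.95 MJ/h MAT / 27.5 MJ/h MAD) are **uncertain**: they are garbled in the
source material. They live in one editable file and every entry can be
overridden by a user YAML that names only the keys it changes. Labor/machinery
rows are method-specific: manual methods carry labor coefficients, mechanized
methods machinery coefficients; a nonzero input with no matching row is a
loud lookup error, not a silent zero.

## Benefit bands and composite codes

Each indicator is banded against multiples of its pooled (all-method) mean:
yield is low (≤ 0.8×mean), medium, or high (≥ 1.2×mean); GHG, EB, PFP and
EUE are high (≥ 1.2×mean) or low. Thresholds are exactly multiplier × pooled
mean; "high" is inclusive at the threshold. A record's composite code
concatenates its five letters in the fixed order yield-GHG-EB-PFP-EUE
(e.g. `HY-HG-HB-HP-LE`); the modal code of a method's records is its
*conventional benefit*. Pooled banding is the default because the published
limit table prints a single set of limits, not four; per-method banding is
available by deriving bands on a method subset. The multipliers are
parameters (0.8/1.2 defaults), not fitted quantities.

## Comprehensive scoring (entropy-weighted TOPSIS)

The decision matrix has methods (default) or records as alternatives and the
five indicators as criteria, GHG flagged as a cost. Entropy weights use
min-max normalized columns (cost columns inverted as max − x first), scaled
to proportions; weight_j ∝ 1 − E_j with E_j the Shannon entropy over
alternatives divided by ln m. A constant column gets weight 0; an all-constant
matrix falls back to uniform weights with a warning. TOPSIS uses vector
(root-sum-square) column normalization; closeness = d⁻/(d⁺+d⁻); score =
100 × closeness; ties break by alternative label.

These are the canonical variants of both methods; the normalizations are
package choices since only the method names are standard. Note that entropy
weighting over a 4-row method-mean matrix is dominated by whichever column
happens to spread most — on the published method-mean table it up-weights GHG
enough to move MAT ahead of MT, whereas plain (uniform-weight) TOPSIS on the
same matrix reproduces the published order MT > MD > MAT > MAD. On synthetic
cohorts calibrated to the published yields, the full entropy-TOPSIS pipeline
also ranks MT first. The exact weighting behind the published four scores is
not recoverable from the publication; the package exposes both modes
(`method-means`, `record-level`) and records which was used.

## Decision-path tree

A binary threshold tree over the five benefit values predicts composite
codes: greedy splits maximize Shannon information gain with candidate
thresholds at midpoints of consecutive sorted unique values (the entropy
criterion of ID3 extended to continuous features as in C4.5). Ties break
toward the lowest feature index, then the smallest threshold, making fits
bit-reproducible. Default split: 70% train / 30% test. Pruning is
reduced-error pruning against a validation fold (20% of the training split):
a subtree collapses to a leaf when the leaf classifies the fold at least as
well. Root-to-leaf paths ending in a target code are exported with the leaf's
class probability — *training-set leaf purity*, labelled as such — and
support. Evaluation reports a confusion matrix, accuracy, and per-class
detection prevalence (TP+FP)/total. A bagging ensemble (bootstrap resampled
trees, majority vote, stratified 75/25 split; singleton classes stay whole in
training) is the cross-check; with one unbootstrapped bag it reduces exactly
to the single tree.

## Input→benefit surrogates and the recommendation search

Per method and per benefit, two regressors map the four optimizable inputs to
the benefit: a random forest (200 trees, `min_samples_leaf=5`, variables per
split chosen from {2, 3} by 3-fold cross-validation) and a gradient boosting
machine (≤400 stages, learning rate 0.05, subsample 0.8, iteration count by
early stopping on a 20% validation fraction). Data are split 3:1 train/test;
held-out predictions feed R², RMSE, rRMSE (percent of observed mean) and MAE.
Variable importance is permutation importance on the held-out split, clipped
at zero and normalized to fractions per (benefit, model), reported for both
models side by side. Partial dependence averages predictions over the
empirical distribution of the other inputs, on a grid spanning the observed
5th–95th percentile of the varied input.

Two numerical choices matter when reading optima off tree ensembles:

* `DependenceCurve.peak` estimates a curve's maximizer by a centered moving
  average followed by the vertex of a parabola through the discrete argmax
  and its neighbors — the standard sub-grid peak read-out for sampled noisy
  curves.
* `recommend` runs coordinate descent over a grid (default 9 points per
  coordinate) inside the 5th–95th percentile box (never extrapolating beyond
  training support), scoring each candidate on a *kernel-smoothed* prediction:
  the mean over 64 fixed Gaussian offsets with scale one grid step,
  averaged over both models. Raw point predictions of tree ensembles are too
  noisy to rank adjacent grid points reliably; local averaging removes that
  noise at negligible bias for smooth responses. After convergence each
  coordinate is refined to the parabola vertex through its best grid point
  and neighbors. The objective is a single benefit (GHG minimized, others
  maximized) or the composite TOPSIS closeness of the predicted benefit
  vector in a fixed space anchored at the cohort's method-mean matrix.

The mixed-effects cross-check regresses a benefit on the z-standardized four
inputs with a random intercept per planting method (REML). A singular or
non-finite fit falls back to OLS and is flagged. With only four groups the
fixed effects are identified essentially from within-method variation;
between-method confounding of input levels with method effects is a real
limitation of this design, visible in simulation whenever group input means
correlate with group intercepts.

## Synthetic cohorts

The generator reproduces the study conditions so the whole pipeline runs
without the original data: per-method sizes MT 302, MD 202, MAT 1079,
MAD 139; MT mean inputs N 136, P₂O₅ 78.6, K₂O 143.5, seed 20.5 kg/ha; MD,
MAT and MAD means derived by the published percentage offsets (MAD's seed
mean is not published and defaults to MT's 20.5). Inputs are independent
truncated-at-zero normals with CV 0.15 — the joint input distribution of the
real meta-dataset is unknown, so independence and a mean-preserving
symmetric shape are assumed and documented. Herbicide (3 kg/ha), pesticide
(4.5 kg/ha), labor (300/280 h/ha for the manual methods) and machinery
(15/12 h/ha for the mechanized methods) are fixed per-method constants of
plausible magnitude; they shift the GHG/EB/EUE levels but carry no signal.

Grain yield follows a separable concave response
y = intercept − Σⱼ bⱼ(xⱼ − xⱼ*)², plus N(0, 900²) noise. Curvatures bⱼ are
parameterized as the yield loss at one input standard deviation from the
optimum: 400 kg/ha for N, 250 for K, 200 for seed, with P inert for MT/MD/MAT
and seed inert for MAD (so importance rankings have a planted null). Default
optima sit at 108–110% of each method's mean input, which makes the
within-method correlation of N with yield positive, as the downstream stages
assume. `calibrate_mean_yields` shifts each method's intercept closed-form so
simulated mean yields equal the published method averages (exact at the
calibration seed because the noise is additive). Other indicator means are
*not* calibrated: EB/PFP follow from the accounting, and EUE is dominated by
the straw = grain imputation, so their absolute levels differ from the
published ones even though the cross-method ordering of yield, EB and PFP is
preserved. Conclusions about absolute GHG/EUE levels therefore cannot be read
off the synthetic cohorts.

`validation_config` is a separate, stronger-signal configuration used by the
recovery checks: effects on all four inputs (losses 800–1200 kg/ha at one SD),
optima at ±8% of the means with mixed signs (inside the bulk of the sampled
design), and noise SD 200. The point of the recovery checks is to validate
the search machinery against a known argmax; that requires the argmax to be
statistically identifiable at the available cohort sizes, which a power
calculation for the smallest method (n = 139) fixes at roughly this signal
level. Passing recovery under `validation_config` shows the optimizer finds
identifiable optima to within one grid step; it does not show that optima in
the weak-signal default conditions (or in real data) are estimable to that
precision.

Everything is seeded through `numpy.random.default_rng`; identical
(config, seed) pairs give bit-identical cohorts, and every CSV artifact
carries `# seed` / `# config_hash` provenance headers. No timestamps are
written anywhere, so repeated CLI runs are byte-identical.

## Problem sizes used by tests and the acceptance script

Unit and acceptance tests run the full default cohort (1,722 records) for
accounting, banding, scoring and trees; optimizer-recovery checks run the
full cohort at three seeds with yield-only surrogate fits; the CLI
determinism check uses a 220-record cohort. These sizes keep the whole suite
within a few minutes on one CPU while exercising every stage at the study's
own sample sizes where it matters.

## Known limitations

* The GHG scope is input-embodied only; paddy CH₄ emissions, which dominate
  real rice-field budgets, are out of scope by design.
* Seed and labor coefficient rows are uncertain (see above); absolute EB and
  EUE levels inherit that uncertainty.
* The entropy-TOPSIS scores of the publication are not exactly reproducible
  because the original matrix granularity and normalization are unstated.
* The recommendation search optimizes over a per-method box of the four
  inputs; it cannot propose changes to pesticide, labor or machinery, and it
  assumes the surrogate generalizes inside the box.
* Single-season, single-system data; no weather or soil covariates.
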