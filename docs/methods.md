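# Methods

This note documents the models, procedures and numerical choices behind
`hmcprog`, and what the synthetic-data generators do and do not emulate.

## Scientific setting

5-hydroxymethylcytosine (5hmC) is the stable oxidation product of 5mC and a
mark of active demethylation, enriched over the gene bodies of expressed
genes. The 5hmC-Seal assay chemically labels and captures 5hmC-containing DNA
fragments; sequencing them yields, after alignment and deduplication, a table
of fragment counts per genomic feature (gene body, promoter, enhancer peak)
per sample. `hmcprog` implements the analysis path from such count tables to
a cancer-progression risk model for gastric premalignant lesions, plus the
cohort-epidemiology layer (incidence, Kaplan–Meier, Cox, nomogram, SIR) used
to characterize progression risk in a large gastritis follow-up cohort.

Patient-level data for the motivating study are not publicly deposited, so
everything here is exercised on synthetic data with known ground truth. The
published real-data figures (e.g. a validation AUC of 87.5% for a nine-gene
panel) are therefore *not* reproduction targets; what the tests establish is
that each stage recovers what was planted under matched sample sizes.

## Synthetic data

**Counts.** Feature–sample counts are negative binomial with mean
`mu_gs = s_s * b_g * 2^(delta_g * I[case]) * 2^(gamma_gb)` and variance
`mu + phi * mu^2`. Defaults: 21 cases vs 48 controls (the profiled
sub-cohort's sizes), ~20k gene bodies, baseline means log-uniform on
[20, 500], dispersion `phi = 0.2` (typical for gene-body 5hmC-Seal counts),
library size factors uniform on [0.5, 2] rescaled to geometric mean 1.
`phi = 0` degenerates to Poisson, which the moment tests use.

**Batch effects** are per-feature log2 shifts drawn at a configurable scale
and centered across batches. A feature-*constant* per-batch shift is
mathematically identical to a library-size effect and is absorbed entirely by
median-of-ratios normalization; per-feature shifts are what make batch
adjustment observable and its recovery testable against the recorded truth.

**Cohorts.** Event times are exponential at hazard
`baseline * exp(sum of log HRs)` with administrative censoring — the
proportional-hazards generating model matching the Cox fitting surface.
Default mixes and log hazard ratios mirror the gastritis cohort's baseline
composition and multivariate hazard structure (dysplasia vs inflammation
HR ≈ 4.7, atrophy/IM ≈ 1.6, female ≈ 0.46, age-group gradient). Ages are
uniform within age-group bounds (70+ capped at 94); only group membership
matters downstream. Weibull or time-varying hazards are out of scope.

**Profiled sub-cohort.** `simulate_panel_cohort` generates the 21/48
case–control set used for risk-model evaluation: clinical covariates are
hazard-structured (cases enriched for dysplasia, older, more often male), so
a covariates-only logistic model discriminates moderately (validation AUC
≈ 0.75 on average), and a nine-gene panel carries a configurable per-gene
mean shift (default 0.8 sd). This mirrors the study design, where lesion
type, age and gender are themselves risk factors.

**What the generators do not emulate:** read-level artifacts (GC bias,
duplicates), correlated features (co-regulated genes), non-exponential
hazards, loss to follow-up patterns, and measurement batch structure beyond
location/scale shifts. Passing tests show procedure correctness under the
stated generating models, not performance on real tissue data.

## Normalization and batch adjustment

Size factors are DESeq-style median-of-ratios: per sample, the median over
all-positive features of the count divided by the feature's geometric mean
across samples, rescaled to geometric mean 1. Features with any zero are
excluded from the median; a pseudocount path is available when no
all-positive feature exists. At the default simulation conditions
(`phi = 0.2`, 2,000 features) the estimator's per-sample sampling error is
~1.3% (median efficiency 1.253/sqrt(n_features) on a log-ratio spread of
~0.47), so per-sample errors of up to ~3% across 69 samples are expected
behaviour, with mean error ~1%.

Downstream analysis uses `log2(count / s_s + 1)`.

Batch adjustment is parametric empirical-Bayes location/scale correction in
the ComBat family: per-feature least squares on batch indicators plus
protected covariates (progression group, z-scored age, gender),
standardization by the unbiased residual variance (denominator `n - p`, which
keeps the EB scale estimates consistent with the per-batch ddof-1 variances
and makes the feature-constant-shift case exactly idempotent), per-batch
location/scale estimates shrunk to their posteriors under a normal /
inverse-gamma prior with moment-matched hyperparameters, then back-transform.
Protecting the group covariate is essential: without it the adjustment
absorbs part of the planted case–control signal. Perfect aliasing of batch
with a covariate raises an error. EB shrinkage is exact when per-feature
batch effects are identical (prior variance 0); on general data a small
residual batch effect remains and strict idempotence holds only
approximately.

## Differential analysis

Effects are `log2((mean scaled case + 1) / (mean scaled control + 1))` from
size-factor-scaled counts — not a GLM coefficient — which keeps the published
correspondence between the 0.26 log2 threshold and a 20% fold change
(`log2 1.2 = 0.263`). Significance is the two-sided Wilcoxon rank-sum
p-value: exact enumeration when `n1*n2 <= 400` and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
corrections. The "empirical p" is the two-sided p divided by two — a
convention inherited from the upstream analysis stack (coin::wilcox_test
usage). Note the halving makes `empirical p < 0.05` equivalent to
`two-sided p < 0.10`, i.e. ~10% of null features qualify, double the nominal
two-sided rate; both values are reported so users can apply either. BH FDR is
the standard step-up procedure (statsmodels). Calls use strict inequalities
at the thresholds.

The candidate screen fits, per feature, an unpenalized logistic model of case
status on the feature plus z-scored age and gender, and keeps features with
Wald p < 0.01. Perfect separation keeps the feature with p recorded as 0 and
a flag — the screen only ranks candidates, so a penalized refit is not
warranted at this stage.

Sample clustering uses 1 − Pearson correlation with average linkage; samples
are ordered lexicographically before linkage so ties resolve deterministically.

## Stability selection

The panel-selection procedure: stratified bootstrap of the training samples
(preserving the 14:32 case:control ratio), per bootstrap a stratified 5-fold
CV over an (alpha, lambda) grid for the elastic-net logistic model, refit at
the chosen pair, conversion of coefficients to importance scores, and marking
of features with importance > 20; features marked in ≥ 80% of bootstraps form
the panel.

The penalized objective is mean binomial deviance
`+ lambda * (alpha ||b||_1 + (1 - alpha) ||b||_2^2 / 2)` with internal
standardization and an unpenalized intercept, solved by IRLS plus cyclic
coordinate descent with soft-thresholding, active-set sweeps and warm starts
along decreasing lambda paths (numba-compiled; convergence at max coefficient
change < 1e-7 for final fits, 1e-5 inside CV). scikit-learn's saga solver is
the independent cross-check in the tests (`C = 2 / (n * lambda)` maps its
objective onto this one); it is not used as the engine because it is orders
of magnitude slower on the p >> n paths this procedure iterates.

The importance metric is the max-scaled standardized coefficient magnitude,
`100 * |b_j| sd(x_j) / max_k |b_k| sd(x_k)` — a 0–100 variable-importance
scale on which a ">20" cutoff is meaningful. CV ties break toward larger
lambda, then larger alpha (parsimony). Per-bootstrap seeds derive from the
master seed by a counter.

Default grids follow the procedure's stated ranges (alpha 0.05–1.0 in 20
steps, lambda 50 log-spaced points in [1e-5, 1], 100 bootstraps). Tests and
the acceptance script run the same procedure with alpha {0.05, 0.3, 1.0},
lambda 6 log-spaced points in [10^-2.5, 1] and 20 bootstraps — sizes chosen
for single-CPU desk-scale runs.

**A caution on small-n selection.** At n = 46 with 2,000 independent
features, the realized standardized group difference of a null feature has
standard error 0.32, so the most extreme null features reach |d| ≈ 1.0–1.2
*within the dataset*. Such features are genuinely associated with the labels
in every CV fold and bootstrap of that dataset and are statistically
indistinguishable from moderately planted signal (e.g. 1.2 sd). Two
consequences, both verified by simulation in the test suite: (i) planted
1.2-sd features cannot be jointly separated from the top null features with
high per-replicate success by *any* threshold on the data — an oracle that
thresholds on realized effects succeeds in only ~35% of datasets; (ii) on
pure noise the panel is typically *not* empty — the top realized-noise
features recur across bootstraps and are retained. The two corresponding
acceptance-style tests assert the stricter idealized behaviour and fail; they
are kept failing deliberately as documentation of this small-sample limit.

## Risk model and evaluation

The final model is unpenalized maximum-likelihood logistic regression (IRLS,
tolerance 1e-8, ≤ 50 iterations) of progression status on the panel features
plus gender, z-scored continuous age and lesion type (two indicators,
inflammation reference). Detected separation (divergence, singular weights)
triggers a ridge-1e-6 refit with a flag. An optional cohort-hazard offset —
the Cox linear predictor entering with coefficient fixed at 1 — implements
the most literal identifiable reading of "adding hazard ratios into the
model"; it is off by default.

Risk scores are the linear predictor (same ROC as the fitted probability, but
immune to sigmoid saturation creating artificial ties at 1.0 under
separation). AUC is trapezoidal over the empirical ROC (ties step
simultaneously; equivalent to the Mann–Whitney statistic, asserted
exhaustively in tests); CIs are stratified-bootstrap percentile intervals
(2,000 reps by default), clipped to [0, 1]. The decision cutoff is chosen on
the validation split: among observed score values achieving specificity
≥ 0.90 there, the one maximizing sensitivity (ties to the larger value);
sensitivity/specificity are then reported on all samples pooled. The split is
stratified 2:1 by case status (21/48 → 14/32 train, 7/16 validation).

## Cohort epidemiology

Kaplan–Meier cumulative incidence is 1 minus the product-limit survival
estimate (lifelines). The Cox model maximizes the Breslow partial likelihood
by Newton–Raphson with step-halving (tolerance 1e-8, ≤ 25 iterations),
standard errors from the inverse observed information, and the Breslow
baseline cumulative hazard for absolute-risk conversion; lifelines is the
independent oracle in tests (identical on tie-free data). Monotone
likelihoods (perfectly separating covariates) raise with the last iterate.

Nomogram points rescale each covariate's contribution `beta_j (x - x_ref)` so
the largest `|beta * range|` spans 0–100; total points map back to the linear
predictor, and survival at a horizon follows from the baseline cumulative
hazard. SIR is observed events over `sum(rate * person-years)` across
age × gender (× calendar) strata; the bundled reference rate table is
synthetic, shaped like East-Asian gastric-cancer incidence gradients, not a
registry product. The 2×2 chi-square is Pearson without continuity correction
(Yates optional). Two-sample power uses the noncentral t with
`ncp = d sqrt(n1 n2/(n1+n2))`; note that 80% power at n = 21/48 corresponds
to d ≈ 0.79–0.80 only approximately — the utility computes ~0.83 power at
d = 0.783, and the function is provided as a general tool rather than forced
to any particular pairing.

**Cohort fixture.** `hmcprog.fixtures.table12_cohort` reconstructs a
29,176-patient cohort whose marginal counts match the published baseline and
outcome tables; percentages, person-years (370,561.99) and the 12.2-year
median follow-up are then *computed*, not asserted. Two printed age-group
cells are inconsistent with their own row/column totals and are reconciled by
absorbing the discrepancy into the 70+ cells; event patients carry their
diagnosis-age group. The joint (gender × age) distribution within lesion
strata is a greedy transportation fill — only margins are faithful.

## Problem sizes in tests and the acceptance script

Cohort arithmetic runs at the full 29,176-patient fixture (seconds). Cox
recovery uses n = 50,000; SIR calibration n = 40,000. Differential and
screening calibrations use 2,000 features at the 21/48 design. Stability
selection runs 4 (script) or 10 + 20 (tests) replicates at 2,000 features
with the desk-scale grids above. Risk-model evaluation averages 25 seeded
replicates. These sizes are the package's chosen defaults for reproducible
single-CPU runs.

## Known limitations

- Features are simulated independently; correlated blocks (co-methylated
  domains) would change stability-selection behaviour.
- ComBat here is the parametric variant only; the nonparametric EB variant is
  not implemented.
- The exact Wilcoxon path requires tie-free data; tied small samples fall
  back to the corrected normal approximation.
- Nomogram rendering (the graphic itself) is not produced, only the point
  scales and survival mappings.
- The "empirical p" halving rule is reproduced verbatim; its statistical
  meaning (a one-sided p under no ties) is documented rather than reformed.
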