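# Methods

## Data model and conventions

Expression matrices are probes × samples on the log2 intensity scale
throughout (`p × n`, matching the orientation of the SVD projection).
Clinical tables carry distant-metastasis-free survival (DMFS) as `time` in
months and a 0/1 `event` flag, plus ER/PGR/ERBB2 status, age, tumor size and
grade. Missing expression values are rejected rather than imputed; there is
no principled imputation rule for this design and silent imputation would
bias the screen.

Z-scoring uses the sample standard deviation (ddof = 1); the convention is
stated explicitly because the two choices differ by a factor of
√(n/(n−1)) that would propagate into the Cox screen scores. Each dataset is
z-scored independently — training statistics are never applied to a
validation set, so a validation cohort can be scored without access to
training-set means and variances.

## Preprocessing

Quantile normalization maps each sample column onto the mean-of-sorted-
columns reference. Tied values within a column receive the mean of the
reference values at their tied ranks — this keeps ties tied and makes the
transform idempotent, which the tests assert. Background filtering keeps a
probe when its detection flag is true in at least `min_fraction` of samples;
the default 0.75 is configurable because detection-call conventions differ
between feature-extraction pipelines and no single fraction is canonical.
Replicate probes (identical probe ids spotted multiple times on a chip)
collapse to the per-sample median: robust, and exactly reproducible as an
order statistic in tests. Background *correction* (e.g. normexp) is
deliberately not implemented: the synthetic data are generated
background-free and the preprocessing entry point is the documented
extension seam for platform-specific correction.

## SAM differential screening

The moderated statistic is `d_i = (mean_A,i − mean_B,i)/(s_i + s0)` with the
pooled standard error
`s_i = sqrt{(1/n_A + 1/n_B) · (SS_A + SS_B)/(n_A + n_B − 2)}`; with `s0 = 0`
and equal group sizes, `d` is the classical pooled-variance t statistic (an
oracle test asserts this). The fudge factor `s0` follows the min-CV search:
candidates are the 0,5,…,100th percentiles of `s`; for each candidate the
coefficient of variation of window-wise median absolute deviations of `d`
(windows = s-quantile bins) is computed, and the minimizing candidate wins,
ties to the smallest. One caveat found during development: under a purely
homoscedastic null, where numerator and `s` are independent, this criterion
legitimately drifts to a high percentile of `s` — the CV decreases
monotonically in `s0` there. This does not affect FDR calibration or power
(both are tested), but `s0` should not be interpreted as an estimate of a
"true" variance offset.

False-discovery rates come from label permutations (default 200, seeded;
exhaustive enumeration replaces sampling when the label multiset admits at
most that many distinct splits, which also makes small-fixture q-values
seed-free). For each cutoff `c` on |d|, expected false positives are
`pi0 · mean over permutations of #{|d*| ≥ c}`; `q_i` is the minimum
estimated FDR over all cutoffs at which probe i would be called, which
makes q monotone in the |d| ranking by construction. `pi0` is the share of
observed `d` inside the permutation interquartile range divided by 0.5,
clipped to [0.1, 1] to avoid q collapse on tiny fixtures. Symmetric |d|
cutoffs are used rather than the asymmetric delta bands of some SAM
implementations: simpler, and monotone q is guaranteed.

Fold changes are `2^(mean_A − mean_B)`; group A defaults to the
lexicographically first label and is configurable (`numerator=`), so that
outputs can be oriented with the group of interest in the numerator.
Cross-series intersection keeps identifiers significant in every series
with a consistent direction (fold change on the same side of 1 everywhere).

## Subtype assignment

Hierarchical clustering of sample columns uses euclidean distance and
complete linkage, cut at the final merge (k = 2). The cluster with the
higher fraction of clinically ERBB2-positive samples is labeled
`molecular_ERBB2`, the other `basal_like`; an exact tie raises an error
rather than guessing. The intrinsic probe list is an input, not embedded —
any probe list can drive the clustering. The PCA view uses probe-centered,
unscaled data (in the pipeline the input is already z-scored, which makes
scaling moot).

## The supervised-PC signature

The per-probe screen is a single-covariate Cox proportional-hazards fit
with Efron tie handling, implemented as a Newton iteration vectorized
across all probes simultaneously (the screen runs inside cross-validation
folds, so per-probe calls to a general fitter would dominate runtime). It
is cross-checked against lifelines probe-by-probe to 1e-5 in the tests,
including on heavily tied data. Non-convergent probes are flagged and
excluded from selection. The selection score defaults to the raw
coefficient, with a `standardized` (coef/se) option — published "raw
scores" of such signatures are describable either way, and the magnitude
pattern of the published table is more consistent with the standardized
variant; both are provided, neither asserted as the original's convention.

Selection keeps probes with |score| ≥ threshold, *inclusive* — a score of
exactly 1 stays in at threshold 1, as in the published 58-probe table.
Threshold choice by cross-validation uses event-stratified folds (default
10): screen + select + fit on the training folds, project the held-out
fold, and score it by the partial-likelihood-ratio statistic of a fresh
3-component Cox fit on the projected scores; the grid defaults to deciles
of the full-data |score|.

The model stores the thin-SVD factors U and D (all positive singular
values retained for diagnostics; only the first three components enter the
index), the Cox betas, the training index scores and the training quintile
cutoffs. Quantiles use the linear-interpolation convention; ties at a risk
cutoff go to the lower-risk group. Projection of a test cohort uses the
training U and D with the test cohort z-scored within itself, and risk
groups are formed from the test cohort's own quintiles — each dataset uses
its own cutoffs.

Two structural identities are tested rather than estimated: applying the
model to its own training data reproduces the training scores to 1e-10
(`V = Xᵀ U D⁻¹` is exact), and refitting a univariate Cox model of survival
on the training index gives hazard ratio e ≈ 2.718 on *any* cohort with
events, because the index is that model's own fitted linear predictor and
the partial likelihood is stationary at coefficient 1. The latter
reproduces the published training-set continuous HR without any cohort
download — it is a property of the construction, not of the data.

Cox ties use the Efron approximation everywhere. Backward elimination
removes the covariate with the largest Wald p above `alpha_remove`
(default 0.05) and refits until all retained covariates pass; exactly
collinear covariates (|r| > 0.9999) are rejected up front with the pair
named. Kaplan–Meier and log-rank statistics are delegated to lifelines and
verified against hand product-limit and hypergeometric O−E/V oracles on
small instances.

## IHC statistics

Categorical tiers follow the percentage of stained tumor cells: <5% → 0,
5–33% → 1, 34–66% → 2, >66% → 3; the continuous score is intensity ×
percentage (0–300). Dichotomization cutoffs: DUSP6 and phospho-ERK split 0
vs 1–3; DUSP4 splits 0–1 vs ≥2 (the published "2–4" on a 0–3 scale is read
as ≥2). Fisher's exact two-sided p sums all fixed-margin tables no more
likely than the observed one (scipy's convention, which reproduces the
published table p-values to the printed precision); a table with an empty
margin returns p = 1 with a warning rather than failing. Spearman's rho is
the Pearson correlation of mid-ranks; the two-tailed p uses the
t-approximation by default, with exact permutation enumeration available
for n ≤ 10.

## Synthetic data: what it emulates, and what it does not

The generator produces log2-scale Gaussian probe intensities (baseline
means uniform on 6–12, within-group sd defaulting to 0.5 log2 units — the
order of residual variation in normalized array data), two groups of equal
size with group A flagged ERBB2+, planted fold changes uniform on 1.2–4×
with a fair direction coin (screens of this kind report changes on both
sides of 1), a configurable fraction of probes carrying "phosphatase" in
mixed-case descriptions, and optional exact-duplicate replicate probes with
independent noise. Survival is exponential with per-patient hazard
`h_j = h_0 · exp(Σ_k β_k z_kj)` on z-scored planted probes (default h₀ =
0.01/month, 10 prognostic probes with |β| in 0.5–1.0); censoring is an
independent exponential whose rate is solved numerically so the expected
censored fraction hits the configured rate (default 0.4). DE and
prognostic probe sets are drawn disjoint so each screen has an
unconfounded truth. Paired platforms share a random probe subset with
identical planted effects; planted probes are placed inside the overlap so
cross-platform validation has a defined truth, and the generator errors if
the overlap cannot hold them.

All randomness flows from one integer seed through fixed, purpose-specific
sub-streams (truth, expression, survival), so identical configs are
bit-identical and expression can be regenerated without re-drawing
survival.

Deliberately not emulated: array chemistry (one- vs two-color, spike-ins,
spatial artifacts), background signal, batch effects, correlated probe
blocks, and non-proportional hazards. Passing tests therefore demonstrate
the correctness and calibration of the *procedures* under the stated
generative model — not that any particular gene list would replicate in
patient data.

Note on parameter recovery: when several prognostic probes are planted at
once, each probe's univariate Cox coefficient is attenuated relative to its
planted β, because the other planted probes act as omitted frailty. This
is a property of marginal Cox screens, not a bug; recovery-to-truth tests
therefore use a single dominant planted probe, while multi-probe settings
are tested through what the method actually claims — transfer of risk
stratification to a validation cohort.

## Problem sizes

Default test and acceptance runs use cohorts of 286–300 patients (the size
of the public training series the design targets), probe panels of
300–2000, 200 permutations for SAM, 60 global-null screens for the FDR
calibration check, and 20 seeded train/validation pairs for the transfer
check. These sizes give stable Monte-Carlo summaries while keeping a full
run in well under a minute on one core.

## Scope and limitations

Reproducing the published table memberships, the 58-probe selection and the
validation HR of 3.005 requires the original cohorts (GSE51999, GSE2034,
GSE7390, GSE20194, NKI-295); those are encoded as flagged, non-desk
reproduction targets in `phosphosig.reference`, with the caveat that
unknown SAM-implementation and preprocessing versions may prevent exact
membership matches even with the data in hand. Out of scope by design:
normexp background correction, Affymetrix CEL/RMA preprocessing, PAM50
single-sample prediction, pathway enrichment, and co-expression networks.
No penalized Cox, time-dependent covariates or competing risks.
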