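# Methods

`adaptmap` implements an adaptive two-stage regression strategy for
predicting a quantitative blood-pressure phenotype — mean arterial pressure
(MAP) — from clinical covariates and genome-wide SNP dosages, validated by
nested cross-validation of the *entire* selection procedure rather than of a
fixed model.

## Model

The working model is additive:

    y = mu·1 + Z u + f(Z) v + sum_i Lambda_i alpha_i + g(Z, Lambda) beta + eps

where `y` is MAP in mmHg, `Z` the clinical covariate matrix, `f(Z)` columns
for low-order covariate interactions, `Lambda_i` the 0/1/2 minor-allele
dosage of SNP i, and `g(Z, Lambda)` SNP-covariate interaction columns.  MAP
is defined as the convex combination `2/3 DBP + 1/3 SBP`.  Two phenotypes
are materialized: the raw readings ("unadjusted") and the treatment-corrected
readings ("adjusted": +10 mmHg SBP, +5 mmHg DBP for subjects on
anti-hypertensive medication), so the adjusted cohort-mean MAP exceeds the
raw one by exactly (20/3) x medicated fraction.

Nothing about the model is fit directly; the support of `u, v, alpha, beta`
is *discovered* per training fold and only then estimated by an L1-penalized
fit.

## Stage 1 — clinical term discovery by bootstrapped pruned trees

A least-squares binary regression tree is grown (minimum leaf 20, depth cap
10) and cost-complexity pruned.  Candidate terms are read off root-to-leaf
paths of the pruned tree: every splitting feature is a main-effect
candidate; features at adjacent internal (parent, child) nodes form 2-way
candidates; internal (grandparent, parent, child) runs form 3-way
candidates.  A pair or triple with a repeated feature is not a term — a
self-interaction is just a main effect.  Because single trees are unstable,
the fit is repeated on B = 300 with-replacement resamples of subjects and a
term's evidence is the number of trees (not paths) in which it appears.
Terms occurring in strictly more than a cutoff fraction (1, 5, 10 or 20%,
default 5%) of the B trees are kept, and the set is closed under
marginality: interaction components are always added as mains.

Pruning penalties: a standalone `fit_pruned_tree` chooses the
cost-complexity penalty by 10-fold internal cross-validation with the 1-SE
rule, computed with an in-package weakest-link pass over the grown sklearn
tree (the penalty sequence reproduces sklearn's
`cost_complexity_pruning_path` exactly; the test suite asserts this).
Inside the bootstrap, each resample leaves out ~37% of subjects, and those
out-of-resample subjects serve as the validation set for the same 1-SE
penalty choice.  This is honest internal validation at one grown tree per
resample instead of eleven, which keeps a 300-resample, 10-fold-CV analysis
at n = 3000 in the minutes rather than hours range.  Categorical features
enter trees through target-mean ordinal codes (equivalent to CART's optimal
subset split for a least-squares criterion), computed once per bootstrap
pass; term keys stay at the whole-feature level.

## Co-occurrence reduction

Near-collinear features compete inside trees: a bootstrap run uses one or
the other, rarely both.  The dissimilarity between features i and j is the
normalized co-occurrence rate `d_ij = #ij / min(#i, #j)` (trees containing
both over trees containing the rarer one): pure competitors get d = 0,
features that are informative jointly get d = 1.  Average-linkage
hierarchical clustering of d is cut at height 0.5 (both configurable; the
complement formula `1 - #ij/min` is available as an option), and each
cluster is represented by its minimax centroid — the member whose largest
dissimilarity to the rest is smallest, ties broken toward the larger
occurrence count, then lexicographically.  The centroid is always an
existing feature, never a synthetic composite.  Main effects are rewritten
onto centroids; interactions have their components remapped and are dropped
if two components collapse onto one centroid; the result is re-closed under
marginality.

Limitation: the tree-level co-occurrence signal separates competitors
cleanly when one split exhausts a feature's information (binary or coarse
categorical near-duplicates).  Highly correlated *continuous* features can
both appear in a single deep tree — CART approximates a smooth effect with
several cuts and uses the near-copies interchangeably at different nodes —
in which case both survive the reduction and the LASSO arbitrates instead.

## Stage 2 — SNP screening by local fdr and step-up mFDR control

Each SNP is tested one at a time: least squares of y on an intercept, the
stage-1 clinical main effects (dummy-coded), and the SNP dosage, computed
by Frisch–Waugh–Lovell residualization so a genome-wide scan is a single
matrix operation.  The two-sided t p-value maps to a z-value through the
probit of the t CDF (tail-stable; identical to sign(t)·Φ⁻¹(1−p/2) at large
df).  Constant or covariate-collinear dosages are flagged with p = 1, z = 0.
Missing dosages are mean-imputed per SNP.

The z-ensemble gets a two-group empirical-Bayes fit: the mixture density f
by Lindsey's method (Poisson GLM of histogram counts on a cubic B-spline
basis, 7 df, 120 bins), the null N(delta, sigma^2) and its proportion p0 by
central matching (quadratic fit to log f over the central 50% of z), with a
theoretical N(0,1) null available and used automatically below 200
z-values.  fdr(z) = min(1, p0 f0(z)/f(z)).  SNPs are then selected by the
step-up rule: sort fdr ascending and keep the largest prefix whose mean fdr
is at most the marginal-FDR bound q (0.2 or 0.5 in practice).

Calibration: in the regime the screen is built for (hundreds of moderately
strong signals among thousands of SNPs) the realized marginal FDR at
q = 0.2 sits at the bound; the acceptance study (50 replicates, 5000 SNPs,
200 causal at 1.5 mmHg/allele, n = 1000) measures ~0.17–0.21.  With very
few signals on a small panel (single-digit causal SNPs among ~2000) the
density estimate at an observed tail z cannot drop below 1/(m·binwidth),
which exceeds the null density there, so borderline null z-scores receive
optimistic fdr estimates and the step-up rule admits a handful of nulls per
fold.  These false positives are unstable — they rarely survive the
cross-fold intersection — but users screening small sparse panels should
prefer the intersection list or a stricter q.

## Stage 3 — adaptive LASSO fit and validation

Selected terms are encoded as a numeric design: numeric covariates as-is,
categorical covariates reference-coded (first sorted level dropped, columns
named `feature.LEVEL`), SNPs as dosages, interactions as elementwise
products of the encoded components (all dummy-level combinations), always
computed before standardization.  The LASSO standardizes internally,
chooses its penalty on a 100-point path by inner 10-fold CV minimizing
squared error on training data only, and reports coefficients on the
original scale; zero coefficients mark terms the adaptive fit eliminated.
Candidate ("forced") SNPs enter the design like any screened SNP and remain
penalized, so the fit may drop them.

Everything — imputation, bootstrap, thresholding, clustering, screening,
penalty choice — is re-run inside each of K = 10 cross-validation folds
(seeded permutation split into near-equal blocks); the held-out fold is
only transformed and scored.  Predictive quality is R² = the squared
Pearson correlation between held-out predictions and observations, averaged
over folds with a per-fold standard error (sd/√K; the folds share training
data, so this SE is an underestimate).  Stage-to-stage ΔR² uses the same
folds and is therefore a paired comparison.  Analysis variants: clinical
features first with SNP mains and then SNP interactions added
(`non_snp_first`), SNPs screened with no covariate adjustment and clinical
terms added afterwards (`snp_first`), and a forced candidate-SNP list
(`candidate_snps`).  In the SNP-interaction stage the chosen SNP dosages
join the clinical features as candidate splitters in a second bootstrap
tree pass; the screened SNP mains stay in the design as penalized
candidates.

## Covariate imputation

Missing covariates (at most a few percent per feature, missing completely
at random in the generator) are imputed by trees before any selection:
columns in increasing order of missing count, each fitted on the rows where
the column is observed with all other covariates (simple-filled,
ordinal-coded) as predictors — a CV-pruned regression tree for numeric
columns, a depth-capped majority-vote classification tree for categorical
ones.  One pass, no iteration; observed cells are never altered, so the
transform is idempotent on complete tables.  Within cross-validation the
imputer is fitted on training rows only and applied to the held-out rows; a
column complete at fit time but gappy at transform time falls back to the
training median/mode.

## Synthetic cohorts

The generator emulates the data structure this analysis expects, not any
particular cohort's marginals: equicorrelated Gaussian blocks among numeric
covariates (correlated anthropometric/lipid-like subgroups), independent
multinomial categorical factors (e.g. a 4-level field-center factor),
independent SNPs with dosage ~ Binomial(2, MAF), MAF ~ Uniform(0.05, 0.5),
and a latent MAP that is linear in planted mains, planted interactions and
per-allele SNP effects plus N(0, noise_sd²) noise.  Defaults mirror the
emulated study: n = 3138 subjects, 44 covariates (4 categorical), 26%
medicated fraction, ≤2% per-feature MCAR missingness, 8.3 mmHg residual
noise, planted effects of 2–3 mmHg per covariate SD and 1.5 mmHg per allele
sized so the signal explains roughly a quarter of phenotypic variance.  The
default panel of 5000 SNPs stands in for a genome-wide panel; panel size is
a free parameter.

SBP/DBP are derived from latent MAP via an independent pulse-pressure draw
PP ~ N(45, 8²) (floored at 5 mmHg): DBP = MAP − PP/3, SBP = DBP + PP, so
2/3 DBP + 1/3 SBP reconstructs the latent MAP exactly while giving
realistic SBP/DBP spread and high MAP–SBP/DBP correlation.  The medication
flag is Bernoulli(0.26) independent of the phenotype; parameter-recovery
studies therefore target the unadjusted phenotype, where the latent MAP is
observed exactly.  The truth record carries the planted terms, their
coefficients, the causal SNP ids, and the oracle R² =
Var(signal)/(Var(signal)+noise_sd²) with the signal variance computed
empirically.

What passing recovery tests do and do not show: the generator has Gaussian
numeric covariates, exact linear planted effects, MCAR missingness, no
linkage disequilibrium, and no population structure or relatedness.
Recovery under these conditions demonstrates the selection machinery is
consistent and leak-free, not that effect sizes or FDR calibration transfer
to cohorts with skewed biomarkers, LD-correlated panels, or confounded
medication use.

## Problem sizes used by the checks

The medication-adjustment identity is exact arithmetic at any n.  The mFDR
calibration study uses 50 replicates of n = 1000 with 5000 SNPs (200
causal).  The end-to-end recovery run uses n = 3000, 20 covariates, 2000
SNPs (5 causal), B = 300, K = 10; the paired SNP-free ΔR² runs use
n = 2000, 12 covariates, 500 null SNPs at both q = 0.2 and q = 0.5.  Oracle
equivalence suites use 1000 random trees, 1000 random fdr vectors, random
orthonormal designs, and random 6–12 feature dissimilarities.

## Numerical choices and degenerate inputs

Strict inequality at the occurrence threshold (count > cutoff·B).  The
step-up prefix comparison uses a relative 1e-12 tolerance so exact boundary
ties select.  z-values are clipped at ±37 (probit of the smallest positive
double).  fdr values are floored at 1e-12 and capped at 1.  A constant
response yields a root-only tree; a constant prediction vector scores
R² = 0 with a warning; zero-variance design columns are dropped with a
warning; an empty selected term set yields the intercept-only model with
R² = 0.  A z-ensemble with sd < 0.1 is rejected as degenerate.  Ties in the
minimax centroid break toward the larger marginal count, then the smaller
feature name.  All randomness descends from a single master seed through
spawned `SeedSequence` streams, so every operation is bit-reproducible.
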