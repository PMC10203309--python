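# Methods

This note documents the models, numerical choices, and design decisions
behind `declinesig`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Progression phenotype

Annualized FEV₁ decline is the two-point slope
ΔFEV₁ = 1000·(V5 FEV₁ − V1 FEV₁)/t, in mL/year, with t the inter-visit
interval in fixed-length years of 365.2425 days. The primary phenotype
labels the ⌈0.30·n⌉ most negative declines *greater decliners* and the
rest *lesser decliners* — at n = 45 this is 14/31, and ⌈·⌉ is the
convention that reproduces that split (0.30 · 45 = 13.5). The realized
threshold (the least negative decline labeled greater) is reported;
ties spanning the boundary are resolved by stable rank order with a
warning. The alternative threshold scheme classifies by decline
magnitude: rapid > 100 mL/year, decliner 20–100, stable/improver < 20,
with both boundaries assigned to the middle class (the source convention
is ambiguous) and positive slopes always stable. A flag substitutes
percent-predicted FEV₁ into the same slope formula for the
%-predicted-based labeling variant.

## Panel construction

BAL censoring follows the immunoassay conventions: values above an
analyte's upper limit of detection (ULOD) are set to that analyte's
maximum detectable concentration; values below the lower limit (LLOD)
are set to a single global constant, half the lowest minimum detectable
concentration across all analytes' standard curves. Censoring is applied
before total-protein normalization (the ordering is not dictated by the
source protocol; imputing on the concentration scale where the limits
are defined is the defensible choice, and it is recorded here). Analytes
with ≥ 50% of measurements below LLOD are removed — the inequality is
inclusive, so an analyte at exactly 50% is dropped. BAL values are then
divided by the sample's total BAL protein (arbitrary but run-constant
units; a plain ratio), and all analytes are log₂-transformed. Base 2 is
chosen because downstream fold changes are reported on the log₂ scale.

The sex filter runs per analyte: a pooled-variance two-tailed two-sample
t-test by sex on log values, Benjamini–Hochberg adjustment across all
tested analytes, removal at adjusted p < 0.05. It is computed on the
COPD analysis cohort only, before modeling. The merge prefixes analyte
ids with `blood:` / `bal:` so the same protein measured in both
compartments remains two distinct features.

## Univariate screen

Fold change is log₂ of the ratio of arithmetic mean *raw-scale*
concentrations (greater over lesser) — the source describes dividing
average concentrations; computing the ratio of geometric means (mean of
logs) is the main alternative and gives slightly different values. The
t-test runs on log-scale values (pooled variance by default; pooled is
the variant that reproduces the published cohort-table p-value of 0.017
from its summary statistics, Welch does not). Underflowed p-values are
reported as the smallest positive float for volcano plotting.

## PLSDA

A two-class PLS1 model: features autoscaled with calibration mean/SD
(constant features excluded with a warning), response encoded 0/1 and
centered (two-column dummy coding is equivalent for K = 2), latent
variables extracted by the classical iterative NIPALS algorithm with
X-deflation (tolerance 1e-10, ≤ 500 iterations per LV; with a single
response column the loop converges in one pass). With n_lv = rank(X) the
in-sample fit equals ordinary least squares, which the tests verify
against a direct solver, and predictions coincide with scikit-learn's
NIPALS PLS regression (used strictly as an independent cross-check).
Default n_lv = 2. The decision threshold is the midpoint of the
calibration class means of the predicted response (the commercial
toolbox default used in the original analysis is undocumented; the
midpoint is symmetric and deterministic); a tied prediction goes to the
lesser class, the larger calibration class.

**Orthogonalization** rotates the fitted score space so LV1 carries all
response-predictive covariance: the new LV1 score vector is the fitted
centered response, and the remaining basis vectors are Gram–Schmidt
completions within the original score span, so rotated higher LVs are
exactly uncorrelated with the response. Because this is a change of
basis inside span(T), predictions are unchanged (verified to 1e-10);
per-LV explained X-variance is recomputed in the rotated basis while the
total is preserved. The sign convention orients LV1 so the
greater-decliner class mean score is negative (negatively loaded
proteins are comparatively increased in greater decliners). The
operation is idempotent and the identity for single-LV models.

## Signature discovery

Balanced resampling draws, from each class, min-class-size samples
without replacement (subset size 2·n_min). With classes 14/31 the
minority class is fully included in every subset, so ranking variability
comes entirely from majority-class subsampling and per-subset penalty
selection. Per subset, features are autoscaled and an elastic net with
mixing parameter 0.5 (unspecified in the source; balanced L1/L2 is the
default, configurable) is fit to the 0/1 response, the penalty strength
chosen by internal 5-fold cross-validation at minimum deviance over a
30-point automatic grid; an analyte is "selected" when its coefficient
is nonzero at that penalty. Selection frequency = selections /
iterations; ties break by higher mean |coefficient| across selecting
iterations, then analyte id.

The step-forward search fits PLSDA on the top-s ranked analytes for
s = 1…max_size (default cap 100; the source does not state a cap),
scoring each size by stratified 6-fold CV. Accuracy is *balanced*
accuracy — the mean of sensitivity and specificity — which is the only
convention consistent with the trio of published figures (98.4%
alongside 100%/96.8%; raw accuracy would give 97.8%). The optimal size
maximizes CV balanced accuracy with ties to the smallest size. Minimal
signatures are the strictly-filtered steps: size < 15 and CV accuracy
strictly > 0.80. The random-signature null evaluates n_random (default
2000; the source also reports a 1000-variant run, exposed as
configuration) same-sized random feature sets by the same CV and reports
the empirical p = (1 + #{null ≥ observed})/(1 + n_random) plus the
one-sample two-tailed t-test of the null distribution against the
observed value (with a single observed accuracy, the published
two-sample comparison reduces to this).

**Known optimism.** The ranking is computed on the full sample; the
k-fold CV wraps only the PLSDA fit. Selected signatures therefore carry
feature-selection optimism — on pure-noise data the pipeline's optimal
signature still reaches near-perfect CV accuracy, while random
signatures of the same size sit near 50%. Nested cross-validation that
re-ranks within folds would remove this but is deliberately out of
scope, matching the procedure this package implements; the
random-signature null calibrates feature-set specialness, not the
absolute accuracy. Conclusions about real-data generalization should
rest on external validation, not on these CV numbers.

## Evaluation

ROC curves use a threshold sweep with tie handling; the trapezoidal AUC
equals the Mann–Whitney statistic /(n₁n₂) (tested to 1e-12 against a
pairwise oracle). The AUC standard error uses the closed form based on
the Wilcoxon statistic with Q1 = A/(2−A), Q2 = 2A²/(1+A). Two AUCs from
the same samples are compared by
z = (A₁−A₂)/√(SE₁² + SE₂² − 2·r·SE₁·SE₂); r is obtained from the average
within-class Pearson correlation of the two score vectors via a lookup
grid. The original published grid is reproduced here by Monte Carlo: the
correlation of two Wilcoxon AUC estimators under a binormal model with
correlated scores, computed on a ρ × A grid (6000 replicates per cell,
50 cases/50 controls) and frozen into the source; a simulation oracle in
the tests confirms the mapping. The cross-validated ROC pools
out-of-fold predicted responses (the pooling convention is not stated in
the source). The association of LV1 scores with decline uses OLS with
covariates (age, race, height, sex, baseline FEV₁ %predicted, smoking
status, pack-years, ICS use), reporting the score coefficient, its
t-based p, and the unadjusted Pearson r.

## Profiles

PCA is computed on mean-centered, variance-scaled data (full SVD,
deterministic signs). The reduced Hotelling T² of a sample is its T²
over the retained components divided by the 95% control limit
k(n−1)/(n−k)·F₀.₉₅(k, n−k); samples with reduced T² > 2 are flagged and
removal runs a single pass followed by one refit. The permutation test
statistic is the Euclidean distance between group centroids in the
PC1–PC2 plane (the source names the test but not the statistic);
p = (1 + #{perm ≥ observed})/(1 + n_perm) with default n_perm = 10000.
Hierarchical clustering uses 1 − Spearman correlation between sample
profiles as distance with average linkage, cut at two clusters, clusters
mapped to classes by majority (ties toward the larger class), and the
dendrogram exported as Newick text. One-way ANOVA on component scores
supports Tukey, Dunnett (against a named control), Holm–Šídák and
Bonferroni post-hoc families.

## Synthetic cohorts

The generator emulates the study's statistical structure. Defaults: 14
greater / 31 lesser decliners plus 40 reference participants with
preserved spirometry; group decline means −104.6 ± 32.0 and
−28.8 ± 21.5 mL/year; follow-up 6.31 ± 0.86 years (drawn as integer
days); baseline FEV₁ and %predicted moments per class; sex proportions
85.7%/54.8% male, reproducing the confounding the sex filter targets;
1305 blood and 48 BAL analytes; 8 sex-associated blood analytes at 2.0
SD; 23 BAL analytes constructed (via empirical-quantile LLOD placement)
to fail the ≥ 50% rule exactly, with ULODs leaving the top observation
censored.

Concentrations are log-normal — Gaussian on the log₂ scale with
analyte-specific baselines and spreads — an assumption, since the
aptamer platform's RFU distribution family is not published. The planted
signature is *co-varying*: its members (default 20, one in BAL,
mirroring the 51/1 blood/BAL split of the published signature) share a
latent module factor giving pairwise |r| = 0.3 (typical within-module
proteomic co-expression), with alternating effect signs and a marginal
standardized class difference of exactly `effect_size` (default 1.5) on
the log scale. A network of co-varying proteins — individually weak,
jointly discriminative — is the premise of this class of analysis; a set
of independent strong markers would contradict it.

Decline classes are *definitional*: declines are drawn from the two
component distributions, then the n_greater most negative realized
values are the greater class — exactly how a percentile-dichotomized
phenotype is defined — so percentile labeling round-trips the generated
truth exactly. ΔFEV₁ is drawn first and V5 FEV₁ back-computed from V1,
the day count and the slope formula, so recomputing the slope from
volumes and dates is exact. TEPPS (the smoking-history reference group)
reuse lesser-decliner analyte parameters, reflecting the finding that
reference profiles resemble lesser decliners.

What passing tests show — and don't: the generator validates the
machinery (recovery power, null calibration, determinism, censoring
logic) under a known truth. It does not model assay chemistry, plate or
batch effects, heavy-tailed or platform-specific distributions,
missingness, or more than two visits, so passing tests quantify
algorithmic correctness, not expected performance on real cohorts.

## Problem sizes in the automated checks

The test suite and acceptance script run the discovery at the full
feature dimension (1305 + 48 analytes) with 200 elastic-net iterations,
a step-forward cap of 40, and 200-variant random nulls — enough
iterations for stable frequency rankings at a few minutes per run; the
2000-iteration default remains the configured production setting.

## Known limitations

- Feature-selection optimism of the non-nested CV design (above).
- The elastic net uses the Gaussian deviance (least squares) on the 0/1
  response; a binomial elastic net is the main alternative and can rank
  features slightly differently near separation.
- The Hanley–McNeil correlation grid is a Monte-Carlo reconstruction of
  the published lookup table, not a transcription of it.
- The orthogonalization and decision-threshold conventions of the
  commercial PLS toolbox used in the original analysis are unpublished;
  the equivalents here satisfy the documented invariants (prediction
  invariance, response-orthogonal higher LVs) but need not match that
  implementation's numbers on shared data.
- With strongly informative planted signatures the step-forward curve
  saturates early and the smallest-size tie-break yields compact
  signatures; the optimal signature is then a subset, not a superset, of
  the planted module.
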