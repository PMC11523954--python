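# Methods

## The problem

Primary androgen deprivation therapy (ADT) is the backbone treatment for
advanced prostate cancer, but a substantial fraction of patients progress to
castration resistance within two years, and clinical covariates alone
(PSA, Gleason score, TNM stage) predict this poorly. `pwlscore` implements a
pipeline that predicts the 2-year responder/non-responder status from mixed
clinical and SNP-genotype features, distils the fitted model into a simple,
auditable risk score, evaluates prognosis stratification on time-to-event
endpoints, and quantifies how a genotype-driven score would shift across
ancestral populations.

## The point-wise linear model

The core estimator is a *point-wise linear* (PWL) classifier. A generator
network g_θ maps each preprocessed feature vector x ∈ ℝ^d to a
sample-specific logistic model

    g_θ(x) = (w(x), b(x)) ∈ ℝ^{d+1},    p(x) = σ(w(x)ᵀx + b(x)).

Every prediction is therefore a linear model whose coefficients can be read,
ranked and aggregated per sample, while the generator can still encode
interactions — for instance an effect whose sign flips between latent
subgroups — that no single global linear model can express.

**Architecture.** The generator uses dense mesh connectivity: hidden layer
l receives the concatenation of the raw input and all previous hidden
outputs, and the linear head reads the full concatenation [x, h₁, …, h_L].
Defaults: L = 3 hidden layers of width 64, rectified-linear activations, a
linear head initialized near zero so training starts at the null model
(w, b) ≈ 0. The dense shortcuts keep the function close to
"global-linear-plus-corrections", which is the intended inductive bias for
small cohorts.

**Training.** Full-batch Adam (learning rate 10⁻³, 500 epochs) on mean
binary cross-entropy with an L2 penalty (`weight_decay`, default 10⁻³) on
the generator weight matrices. An optional penalty λ‖w(x)‖² on the *emitted*
weights exists for very small cohorts but is off by default. Early stopping
monitors loss on a stratified 20% internal holdout with patience 50 and
restores the best parameters; it disables itself below n = 20 or when a
holdout would lose a class. Gradients are analytic (hand-derived for the
mesh topology) and checked against finite differences in the test suite.
All randomness — initialization and the holdout split — flows from
`random_state`, and a fit is bit-reproducible.

**Hyper-parameter selection.** Stratified 5-fold cross-validation on the
discovery cohort, scored by held-out AUC; the default grid is
weight_decay ∈ {10⁻⁴, 10⁻³, 10⁻²} × depth ∈ {2, 3}. The discovery-cohort
performance reported for the selected point is its mean fold AUC; validation
metrics always come from a single refit on the full discovery cohort. The
same fold partition (same k and seed) is reused for the comparators —
elastic-net logistic regression (saga) and gradient-boosted trees
(xgboost) — so comparisons are head-to-head. Stratification is a design
choice to avoid fold-level class degeneracy at n ≈ 80.

## Preprocessing

Fitted on the discovery cohort only and frozen: binary variables recoded to
±1 (lower observed category → −1), quantitative variables z-normalized with
the discovery mean and sample SD (n − 1), SNP genotypes coded additively
(minor-allele count 0/1/2 treated as quantitative — matching the
cross-population effect formula, which weights heterozygotes once and minor
homozygotes twice), and missing values set to exactly 0 *after* coding, so a
missing lab value sits at the discovery mean. Zero-variance features raise a
named error rather than silently producing NaNs. Ordinal covariates
(Gleason score, extent-of-disease grade, N/M-category) are treated as
quantitative so each carries a single weight.

## Importance scores and simple prediction scores

For sample j the importance of feature i is |w_ji|, the magnitude of the
sample's own coefficient (an |w_ji·x_ji| mode is available behind a switch;
the weight-only reading was chosen because the distilled score should rank
*parameters*, not parameter-value products, and it reproduces the intended
behaviour in planted-signal simulations). Per sample, the top
k = max(1, ⌈0.10·d⌉) features are "ranked" (ties broken by descending
importance, then stable feature order); the importance score s_i is the
fraction of samples ranking feature i, so Σ_i s_i = k exactly. Features
with s_i ≥ 0.1 are extracted and signed by the median of their sample-wise
weights over the discovery cohort (zero medians are dropped with a
warning). The simple prediction score is S_j = Σ σ_i·x_ji over the
extracted features, computed on the preprocessed scale: the published score
ranges for models of this kind (≈ −1.4 to 13.2 over 12 features) are
consistent with unit-scale inputs and not with raw laboratory units, so the
preprocessed reading is the default and a raw-value mode is a config
switch. Pooled discovery + validation scores are cut into quartile groups
Q1–Q4 (lowest quarter = Q1) of near-equal size, ties broken by stable
sample order.

## Outcome definitions

PSA progression requires one measurement that simultaneously (i) is
≥ 2.0 ng/mL, (ii) is ≥ 1.5 × the running nadir (the minimum over strictly
earlier measurements), and (iii) closes three consecutive strict rises with
≥ 7 days between consecutive measurements (four ascending points). The
earliest qualifying day is the progression day. Radiographic progression is
accepted as an externally supplied date, never computed. At the 2-year
landmark (730 days): progression on or before the landmark → non-responder;
follow-up past the landmark without progression → responder; censored
before the landmark without progression → excluded, with the exclusions
counted and reported. The 7:3 discovery/validation split is simple random
assignment with validation size ⌊0.3·n⌋.

## Survival evaluation

Kaplan–Meier curves per quartile group (exported as step-function
coordinate tables), the k-group log-rank test (χ² with k − 1 df), and
Harrell's C-index with standard comparable-pair and tie rules (tied
predictions count ½; equal times are comparable only when exactly one is an
event). Simple scores are oriented "higher = responder = better prognosis",
so risk = −score inside the C-index and C > 0.5 means correct ordering.
Quartile × response association uses the chi-square test without continuity
correction on the 4×2 table; a Q1-vs-Q4 2×2 collapse is also emitted, and
expected cell counts < 1 set a warning flag rather than failing.

## Cross-population effect of a signed SNP panel

Under Hardy–Weinberg equilibrium at minor-allele frequency p, a SNP with
simple-score sign c contributes c·2p(1 − p) + 2c·p² = 2cp to the expected
score in a population. Summing over the panel gives the expected
genetic-background shift of the score; the packaged 19-SNP panel (16 with
available 1000 Genomes frequencies) yields −0.16 (SAS), 1.70 (AFR), −1.20
(EUR), 0.08 (AMR) and 0.94 (EAS) at the 2-decimal display convention —
higher values meaning a higher expected probability of responding to ADT.
Coefficients are the ±1 simple-score signs, not median weights; internal
sums are unrounded and rounding happens only at display. SNPs without an
available frequency stay in the panel but are excluded from sums and
counted.

## The synthetic cohort generator

No patient-level data are public, so the generator emulates the assumed
structure: binary comorbidities Bernoulli(prevalence 0.5 by default),
quantitative labs Gaussian on a coded N(0, 1) scale and mapped to plausible
raw units via a shipped profile (PSA log-normal); genotypes drawn
independently per SNP under HWE at configured MAFs; a responder label drawn
from inverse-logit(intercept + βᵀx_coded), with an optional heterogeneity
spec that swaps in subgroup-specific β keyed by a binary feature's ±1
coding (the subgroup feature remains in the matrix, so a flexible model can
recover the interaction); and PFS/CSS/OS times exponential with
log-hazard = −hazard_scale·η, so high-score responders live longer —
matching the direction the survival evaluation assumes. Censoring is
applied per sample with the configured probability, the censored time drawn
uniformly on (0, T), which realizes the configured rate directly.
Missingness is injected completely at random into clinical features only
(array-called genotypes are assumed complete). The default cohort profile
is n = 119, 4 binary + 19 quantitative clinical features, a 46-SNP panel,
5% missingness and 25% censoring.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population structure, genotyping error, informative censoring,
informative missingness, or the true marginal distributions of the study's
covariates (not public). Passing tests therefore demonstrate correctness of
the procedures under the assumed model, not predictive performance on real
patients.

## Problem sizes used in the checks

The repeated-seed simulation checks use n = 2000: planted-signal recovery
(3 true effects of ±1.5 among 30 features, 10 seeds) and the subgroup-flip
advantage of the PWL model over elastic-net logistic regression (d = 10,
effects ±2 on three features, 10 seeds). Null calibration of the log-rank
and chi-square tests uses 1000 simulations at 50 samples per group, sizes
chosen for asymptotic adequacy of the reference distributions. Structural
pipeline tests run a 200-sample cohort with reduced generator width and
single-point grids; these sizes exercise every code path while keeping the
suite quick.

## Known limitations

- The original deep-unified-network topology and training schedule are not
  recoverable from the source material; the mesh architecture here is a
  minimal faithful concretization, and recovered feature lists will not
  match the published ones (private cohort).
- The sample-wise importance formula is reconstructed (absolute weight);
  the alternative reading ships behind a switch.
- Between-model inference on C-index differences is out of scope; only
  per-model values are reported.
- The split rule ⌊0.3·n⌋ gives (84, 35) at n = 119; the published (82, 37)
  reflects the study's own randomization and post-split exclusions and is
  not reproducible by any deterministic rounding.
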