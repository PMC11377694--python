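# Methods

`rumenstab` analyses the temporal stability of a repeatedly sampled
microbiome — the motivating design is a growing-finishing beef-cattle trial
with 20 steers on two basal diets (concentrate vs forage), two breeds and a
feed-additive treatment, each animal sampled at six timepoints roughly a
month apart — and asks three questions: is community diversity stable over
time; which individual features are *repeatable* (attributable to persistent
between-animal differences); and which features keep a *stable association*
with host performance and methane traits, including the host-genomic
component of those traits via GBLUP breeding values.

## Compositional preprocessing

Count tables are compositional, so per-feature modelling happens on
log-ratio scales. Features are first filtered: a feature must be nonzero in
every sample and have mean relative abundance ≥ 1e-5 (0.001%); both rules
exist because very rare features carry mostly sampling noise. "Present in
every sample" is the strict reading of per-animal prevalence (a config
switch relaxes it to presence in any timepoint of each animal). Diversity
analyses deliberately use the unfiltered counts.

Transforms: CLR (log x minus per-sample log mean) or ALR against a
reference feature. The reference is chosen by a deterministic two-step
rule: among the candidates in the top 10% by Procrustes correlation between
the ALR geometry and the CLR geometry, pick the one with the smallest
variance of log abundance, ties broken by column order. The two criteria
(geometry preservation, quiet reference) are the standard ones for ALR
reference selection; the logratio literature states them as joint desiderata
without a single combination formula, so the top-fraction-then-minimum rule
here is this package's documented operationalisation. A pseudocount (default 0.5, added
only when zeros are present) keeps the transforms total; natural logs
everywhere.

Procrustes correlation is computed as
`sum(singular values of Yc' Xc) / sqrt(tr(Xc'Xc) tr(Yc'Yc))` on
column-centred matrices — invariant to rotation and global scaling of
either argument.

## Diversity

Alpha diversity is the Shannon index divided by `ln S` (the maximum for the
sample's richness S), a pure evenness measure in [0, 1]; it is defined as 0
for single-feature samples. Its timepoint test is a mixed model (timepoint
fixed, animal random, REML) with a Wald chi-square on the timepoint factor
and, if significant, Tukey-style (studentized-range) pairwise contrasts of
model means.

Beta diversity is Bray-Curtis on raw counts. PERMANOVA uses the Gower sum-
of-squares decomposition: pseudo-F = (SS_between/(a-1))/(SS_within/(n-a)),
R² = SS_between/SS_total, p by seeded label permutation with the +1
correction; 999 permutations by default. Post hoc pairwise PERMANOVAs are
Bonferroni-adjusted (the pairwise tool the field uses defaults to
Bonferroni-style adjustment). The dispersion test embeds the samples by
principal coordinates (negative eigenvalues truncated), computes each
sample's distance to its group centroid, and permutes those distances
across groups around a one-way ANOVA F. NMDS minimises Kruskal stress-1;
the optimiser is scikit-learn's non-metric MDS run from a classical-scaling
start plus seeded random restarts, and the reported stress is recomputed
from the final configuration with an isotonic regression of configuration
distances on dissimilarity ranks (ties averaged).

## Repeatability mixed models

Every per-feature model has a single random effect:
`y = X beta + Z u + e`, `u ~ N(0, sigma2_w I)` over animals. Writing
`lambda = sigma2_w / sigma2_e`, the marginal covariance is
`sigma2_e (I + lambda Z Z')`; after one eigendecomposition of `Z Z'`
(shared across all features on the same design) both ML and REML reduce to
1-D profile likelihoods in lambda, maximised by bounded scalar search
(tolerance 1e-8, lambda in [0, 1e6], boundary fits flagged). In the
balanced case the REML optimum equals the closed-form one-way ANOVA
estimators, which the tests exploit as an oracle.

Conventions:

* Fixed-effect model comparisons (does timepoint, or the feed additive,
  improve the model?) use **ML** fits — REML likelihoods are not comparable
  across fixed-effect structures. The verdict requires both a Bonferroni-
  adjusted LRT p < 0.05 *and* a lower BIC for the richer model.
* Repeatability `Rpt = sigma2_w / (sigma2_w + sigma2_e)` uses **REML**, with
  diet + timepoint fixed (timepoint kept even when non-significant);
  within-diet analyses subset the samples and keep timepoint only.
* Rpt significance is the likelihood-ratio test of `sigma2_w = 0` with the
  boundary mixture `0.5 chi2_0 + 0.5 chi2_1`. Rpt p-values are deliberately
  **not** multiplicity-adjusted: the core microbiome is defined by raw
  p < 0.05, and that convention is inherited here.
* The CON-vs-FOR comparison of Rpt magnitudes for the doubly-core features
  is a paired two-sided Wilcoxon signed-rank test — a distribution-free
  choice for paired bounded quantities, documented here as the package's
  convention.

## Cross-timepoint profile correlations

Transformed abundances are centred per feature on the grand mean over all
samples, each timepoint's animal x feature matrix is flattened animal-major,
and Pearson r is computed per timepoint pair. Centring happens after any
subsetting (a flag switches to all-feature grand means). Pearson r is
invariant to any consistent flattening order; the fixed order exists for
reproducibility of intermediate files.

## PLS-VIP stability selection

Traits are first residualised by OLS on allocation-day weight and the basal
diet indicator. Per (trait, timepoint) a 2-component PLS1 (NIPALS) is fitted
with autoscaled predictors (centring + unit variance, the default of the
field's standard PLS tooling; a flag disables scaling). VIP uses the
SSY-weighted formula, so `mean(VIP²) = 1` exactly. Reported explained
variance is the training R²Y (no cross-validation), reported as an
in-sample description of fit.

The longitudinal rule: a feature is **important** for a trait when
VIP > 0.8 in ≥ 4 of 6 timepoints, and **stable** when additionally
max(#positive, #negative coefficients) ≥ 4 (zero coefficients count as
neither sign). Externally supplied biomarker subsets are evaluated by
restricting the predictor set; subset members absent from the data are
reported and dropped.

## Genomic prediction

VanRaden method-2 G standardises each marker dosage by its own
allele-frequency variance and averages cross-products over markers
(`G = Z Z' / m`). GBLUP (`y = X beta + g + e`, `g ~ N(0, G sigma2_g)`) is
fitted by the same 1-D REML profile, now in the eigenbasis of G; EBVs are
the BLUP `lambda G (I + lambda G)^{-1}` residuals. Animal-breeding practice
often solves this model with Bayesian flat-prior Gibbs sampling; REML gives
the equivalent point estimates deterministically, and a seeded
scalar-update Gibbs sampler is
included purely as a stochastic cross-check (tests verify posterior means
agree with REML within Monte-Carlo error). EBV-microbiome association
reuses the PLS machinery unchanged with EBVs as responses.

## The synthetic-data generator

Latent per-feature log abundances follow
`eta = mu_i + delta_i*[diet] + kappa_i*[breed] + tau_it + u_ij + eps_ijt`
with `Var(u)/(Var(u)+Var(eps)) = rpt_i` (total variance 1). Defaults: 20
animals, 6 timepoints, 400 features; baseline `mu_i ~ N(0, 1.5²)`
(log-normal abundance spread — a modelling choice; real abundance
distributions are heavier-tailed than any single parametric family); 10% of features get diet
effects (sd 0.5) and 10% breed effects (sd 0.3); timepoint effects default
to 0 (temporal stability is the null the trial design probes), with an
optional linear "drift" for power studies. Counts are multinomial with
`softmax(eta)` probabilities and library sizes log-uniform in
[5e4, 5e5] — deep-sequencing depths at which multinomial noise is minor
relative to the biological residual. The softmax coupling means realised
ICC on the log-ratio scale deviates slightly from `rpt_i`; recovery tests
therefore measure the estimator on the latent tensor, and tolerance bands
were calibrated empirically.

Traits: 30 planted biomarkers are drawn among the more repeatable features
(their animal effects must carry signal), each with a per-trait weight of
random sign and magnitude uniform in [0.5, 1.5] — a planted biomarker has a
material effect by construction. Each trait combines the standardised
biomarker signal, a polygenic breeding value (weight 0.5 scaled by
`sqrt(h²/(1-h²))`), allocation weight (weight 0.3) and N(0, 0.5²) noise,
then has its sample mean/sd calibrated exactly to the emulated trial's
printed descriptives (FCR 8.29 ± 1.69, ADG 1.42 ± 0.32, DFI 11.30 ± 1.27,
RFI −0.08 ± 0.65, CH4P 183.12 ± 53.12, CH4Y 19.53 ± 5.32 g; allocation
weight drawn N(414.1, 35.7²) kg). Genotypes: allele frequencies
Uniform(0.1, 0.9), dosages Binomial(2, p); an `n_families` option creates
sibling families (within-family relatedness ≈ 0.5).

What the generator does **not** emulate: phylogenetic correlation between
features, zero inflation beyond multinomial sampling, read-level error, and
trait definitions derived from longitudinal weighing. Passing recovery
tests therefore demonstrates correctness of the estimators under a clean
generative model, not robustness to those real-data complications.

## Problem sizes, calibrations and known limitations

* Null calibrations run at 500 replicates: PERMANOVA at 30 samples / 3
  groups / 199 permutations (p-value resolution 0.005 is ample at
  alpha = 0.05), the Shannon Wald test at the full 20 x 6 design. Both
  reject 4.5-7.5% of true nulls in calibration runs.
* Repeatability recovery: 200 features per ICC bin {0.1, 0.3, 0.5, 0.7} at
  20 x 6; per-bin mean error observed within ±0.02.
* Stable-biomarker recovery at trial scale is intrinsically limited: a
  non-biomarker's persistent animal effect can correlate with a trait by
  chance at n = 20 and that correlation persists across timepoints, so
  specificity cannot approach 1. Calibration across eight generator seeds
  gave trait-averaged sensitivity 0.45-0.60 and specificity 0.51-0.60; the
  frozen test bounds (0.35 / 0.45) sit a margin below those minima. The
  same caveat applies to any single-cohort biomarker study of this size.
* GBLUP h² is weakly identified in an unrelated 200-animal panel (the REML
  profile over the variance ratio is nearly flat; Monte-Carlo sd of the
  estimate ≈ 0.3). Heritability recovery is therefore demonstrated on a
  family-structured panel (20 sibling families), where relatedness
  variation identifies the ratio, and reported as the mean over 5
  replicates (Monte-Carlo sd ≈ 0.07). This is a property of the design,
  not of the estimator.
* Training R²Y of 2-component PLS with hundreds of predictors and 20
  animals is high (≈ 95% on the default study) and should be read as an
  in-sample description — not as predictive accuracy.
* The filter's output size is data-dependent; no attempt is made to match
  any particular retained-feature count.
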