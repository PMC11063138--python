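# Methods

## The model

The package operationalizes one idea: a per-participant latent factor *d*
("dilution", more generally the non-disease CSF concentration level)
additively shifts the log-scale abundances of a large fraction of the CSF
proteome. For standardized protein values the working model is

    z_ij = lambda_j * d_i + beta_j^A * a_i + beta_j^T * t_i + eps_ij,

where *a* and *t* are amyloid and tau pathology burdens, lambda_j the
protein's dilution loading, and eps measurement noise. The mean
standardized CSF level y_i (average z-score over the panel) estimates a
scaled version of d_i; a *reference protein* is a high-lambda, zero-beta
protein whose value can replace y_i as an adjustment covariate. Adjustment
is always covariate-style (`outcome ~ predictor + reference + age + sex`),
not ratio-style, though a ratio can be emulated by transforming the
predictor upstream; the covariate form is what produces the sloped linear
cutoff in pg/ml space used for AT(N) grouping.

## The synthetic cohort

Restricted real cohorts cannot ship with the package, so the generator
(`synthetic_cohort`) defines the study conditions, with all latents kept as
ground truth:

* **Size.** 658 participants and a 500-protein, 10-cluster panel — a
  training-split-sized cohort with the panel scaled down ~6x from a full
  discovery library so that every analysis runs at desk scale. The
  protein-count reduction mainly affects how precisely y_i estimates d_i
  (still r ≈ 0.99 at 500 proteins), not the qualitative behaviour of any
  stage.
* **Dilution factor.** d = 0.30·age_z + 0.20·(sex−mean) − 0.35·log-ventricle_z
  + genotype term + N(0,1). Only the *signs* of these coefficients are
  anchored to what CSF cohorts report (level higher with age and male sex,
  lower with larger ventricles); magnitudes are chosen so covariates explain
  a minority of var(d), since no quantitative decomposition is published.
* **Cluster loadings.** Per-cluster mean loadings 0.0–1.2 with N(0, 0.08)
  within-cluster jitter. The top-loading cluster is the planted reference
  cluster: beta^A = beta^T = 0 for all its members.
* **Pathology.** a, t are standard normals with correlation 0.5
  (amyloid–tau coupling; the correlation is configurable). Designated
  panel proteins carry the disease effects: a P-tau181-like protein
  (beta^T = 1.5), an Abeta42-like protein (beta^A = −1.2), and a
  three-protein "disease module" sharing 60% of the tau effect, which gives
  the partial-correlation analysis a genuinely disease-driven correlation
  that must survive reference adjustment.
* **Pathway factor.** A second non-disease factor w is shared between the
  pg/ml P-tau181 analogue and ten "specific candidate" proteins of the
  reference cluster. This reproduces the mechanism by which a single
  well-chosen reference can outperform the global mean level: the mean
  level estimates d almost perfectly but contains essentially none of w,
  while a specific candidate carries both. The Abeta42/Abeta40 pair is the
  canonical instance — here the pg/ml Abeta40 column is generated directly
  from its NPX panel analogue, so adjusting Abeta42 for that protein
  removes both dilution and the shared assay/pathway component.
* **pg/ml biomarkers.** P-tau181 = 12.5 + 6·exp(0.9·t) + 4.5·d + 2.5·w +
  N(0,1.5), clipped at 1 pg/ml — right-skewed, with tau-PET-negative and
  -positive group means/SDs near 19±7 and 33±11, the scale on which the
  conventional 21.8 pg/ml cutoff is meaningful. Abeta40 ≈ 18000·(1 +
  0.16·NPX-analogue); Abeta42 = Abeta40 · (0.100 − 0.050·f(a) + N(0,0.006))
  so that the ratio indexes amyloid and crosses 0.08 near the positivity
  threshold.
* **PET and outcomes.** Continuous SUVR/centiloid values are monotone
  piecewise-linear in the noisy latent burden (pet_noise_sd = 0.5),
  anchored so the conventional cutoffs (SUVR 1.36, centiloid 20) sit at
  the configured prevalence quantiles (tau 0.27, amyloid 0.33); stored
  positivity labels are derived from the continuous values, keeping the
  classification functions exactly consistent with the labels. Conversion
  to dementia is thresholded noisy t among non-dementia participants at
  prevalence 0.12.
* **Missingness.** Values below each protein's lod_quantile (default 2%)
  empirical quantile are recorded missing — censoring, never imputation.
* **Genotypes.** Two Hardy–Weinberg variants (MAF 0.3): one acting on d
  (dilution-mediated pQTL, expected to attenuate under reference
  adjustment) and one with a direct effect on a single reference-cluster
  protein (expected to persist).

What the generator does **not** emulate: batch/plate effects,
heavy-tailed or assay-specific noise, longitudinal drift, realistic LD or
population structure, and any spatial PET detail. Passing tests therefore
demonstrate that the *pipeline logic* recovers planted structure under its
own assumptions, not that real cohorts satisfy those assumptions.

## Numerical and procedural choices

* **Standardization** uses the sample SD (ddof = 1), is fitted on training
  participants only, and is never refit downstream. Missing z-scores are
  excluded from the Eq.-style average (count-weighted mean); imputing zero
  would bias y toward 0 for high-missingness participants.
* **Detectability filter** keeps proteins with missing frequency strictly
  below the threshold, and always keeps fully observed proteins (so a
  threshold of 0 retains exactly the complete proteins).
* **Split** is simple random with plain rounding of n·fraction; an
  optional stratified mode exists but is off by default.
* **Logistic fits** are unpenalized maximum likelihood via a small
  Newton–Raphson solver with step-halving and a 1e-10 Hessian ridge; the
  per-protein reference screen fits ~10^5 such models, which is what makes
  a general-purpose estimator impractical in the inner loop. Agreement
  with scikit-learn's unpenalized solver is asserted in the tests. Under
  complete separation the iteration stops at the cap with large finite
  coefficients; rankings (hence AUC) are unaffected.
* **AUC** is the rank/Mann–Whitney form with half-credit ties, vectorized
  across bootstrap resamples. Cross-validation pools out-of-fold
  probabilities (10 folds, shuffled; redrawn stratified if a training fold
  would be single-class); continuous predictors are standardized within
  training folds. One fold seed is shared across proteins in the screen so
  per-protein AUCs are paired.
* **Bootstrap ROC test** resamples participants with replacement and
  reports p = (#{AUC_b − AUC_a ≤ 0} + 1)/(n_valid + 1), one-sided for "b
  better"; identical inputs give p = 1 by construction. Resamples lacking
  an outcome class are dropped from the count.
* **Embedding/clustering.** t-SNE (PCA initialization, perplexity 30 by
  default — unstated in the literature, so the scikit-learn-era default is
  used) over proteins-as-points; K-means (K = 20 default) on the 2-D map,
  fitted on id-sorted coordinates so the labels are input-order invariant.
  The "semi-supervised" element is expressed as explicit, logged
  merge-override pairs in configuration rather than interactive tuning,
  because interactive t-SNE adjustment is not reproducible. Cluster AUC
  summaries use the population SD so singleton clusters report 0.
* **Adjusted T boundary.** Fit `PET ~ ptau + reference`, convert the
  constant-probability line to pg/ml space. The default operating point is
  the 0.5-probability boundary: published reference-adjusted cutoffs have
  their threshold at the mean reference far above the conventional
  unadjusted cutoff, which a matched-specificity rule cannot produce, so
  the boundary's operating point is treated as refit to PET.
  `match_specificity` and `youden` rules remain available.
* **Candidate selection** requires membership in the winning cluster, an
  AUC gain in both search models, and presence on the validation panel;
  ranking is by mean AUC gain with ties broken by protein id.
* **Partial correlations** are the residual-regression form on
  listwise-complete rows (the precision-matrix form is the independent
  test oracle). ANCOVA contrasts use the pooled residual variance, BH
  adjusted across the pairwise contrasts per protein.
* **Enrichment test** compares the subset mean per feature against means
  of equal-size draws from the background, two-sided around the null
  center, with the (k+1)/(n+1) correction and BH across features.
* **Determinism.** Every stochastic stage draws from an explicit named
  seed in the pipeline config; reruns with one config produce byte-identical
  summaries. Outputs carry a hash of the canonical config serialization.

## Problem sizes

The default pipeline run and the reproduction script use the full default
conditions (658 × 500, 10-fold CV, 2000 bootstrap iterations). The test
suite's calibration checks use 500 simulated replicates with the bootstrap
reduced to 500 iterations, and the directional checks use ten seeded
replicates of the default cohort — sizes chosen so the whole suite stays a
few minutes on one CPU while keeping binomial error on calibration rates
below ~1 percentage point.

## Known limitations

* The mean level is an *average z-score*, not a total protein measure;
  the package deliberately provides no absolute-concentration
  normalization.
* Reference adjustment is linear; strongly non-linear dilution effects
  (e.g. multiplicative on the raw scale with varying protein-specific
  exponents) would only be partially removed.
* With a single global dilution factor the planted reference cluster is
  unambiguous; real panels may contain several overlapping non-disease
  factors, in which case cluster-level rankings can be less stable than
  the ten-seed stability seen here.
* t-SNE layouts are seed-reproducible but not comparable across datasets;
  cluster identities are meaningful only within one fit.
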