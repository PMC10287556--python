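# Methods

`envlink` re-implements, as a tested library, a multi-stage inference
procedure for linking high-dimensional environmental exposures to groups of
psychiatric symptoms in a large population cohort: latent exposure
categories built by cross-validated one-factor confirmatory factor analysis
(CFA), stability-selected sparse canonical correlation analysis (sCCA) with
permutation inference and projection deflation, a three-block extension to
regional brain volumes (msCCA), dosage-based GWAS of the symptom variates
with LD-clumped weighted gene scores, and genotype-moderated brain-mediated
pathway models. Because the motivating cohort data are access-restricted,
every stage is exercised against a synthetic-data generator with known
planted structure; this note records the models, the defaults, and the
design decisions.

## The synthetic cohort

`SimConfig`/`simulate_views` generate one cohort with five linked views on a
shared participant index:

* **Environment.** `n_env_categories` (default 53) category-level columns,
  of which `n_single_item_categories` (34) pass through as raw items and the
  rest fan out into `n_env_raw` (128) one-factor indicator items with
  loading 0.8, so the CFA stage has a true latent to recover.
* **Symptoms.** `n_symptoms` (21) columns.
* **Canonical modes.** Each of `n_modes` modes draws a latent pair
  (t_x, t_y); the generator calibrates the realized sample correlation of
  the pair to exactly r_k (`exact_mode_correlation=True`, the
  `mvrnorm(empirical=TRUE)` convention), so "the planted value" is
  well-defined for a finite cohort. Disjoint support columns in each view
  are noisy indicators of their view's latent with loading
  `indicator_fidelity` (default 1.5, i.e. signal sd 1.5 per unit noise sd).
  The population canonical correlation of mode k is then
  r_k · R_x · R_y where R² = s·a²/(s·a² + 1 − a²) with a² = λ²/(λ²+1) and s
  the support size — about 6% attenuation at the defaults. The default
  fidelity is a deliberate compromise: higher values concentrate the
  cross-covariance so strongly that the L1 bound of the sparse step goes
  slack (the fit is then dense and the selection stage degenerates), lower
  values attenuate the planted correlation. Default mode strengths
  (0.30, 0.15) sit in the range of canonical correlations the motivating
  study reports (0.03–0.22).
* **Genotypes.** Biallelic dosages from two latent AR(`ld_rho`) haplotype
  chains per LD block, thresholded at the allele-frequency quantile; MAF
  uniform on `maf_range`, INFO fixed at 1.0, one gene label per block.
  The default `ld_rho = 0.95` yields adjacent dosage r² around 0.6–0.8,
  the tight within-block LD of imputed cohort data, so the r² > 0.5
  clumping gate has something to thin. Integer dosages by default;
  `continuous_dosage` adds clipped noise to emulate imputed expected
  counts.
* **Mediation chain.** M = a1·X + a3·X·W + e, Y = c′·X + c3·X·W + b1·M +
  b2·M·W + g·W + e, with X the first mode's environment latent and W the
  standardized dosage sum over the moderator gene's variants. The g·W term
  (`w_main_effect`, default 0.3) anchors a marginal genetic association on
  the symptom outcome so the GWAS → clumping → weighted gene score chain
  has a true signal to find; the moderation itself (a3, b2) is what the
  stratified and Model-59 analyses target. The first ~10% of brain columns
  are high-fidelity indicators of M; the rest are noise.
* **Confounds.** Age, sex and assessment center enter every view additively
  and linearly with per-column Gaussian coefficients (scale
  `confound_effect_scale`, default 0.2), so least-squares residualization
  removes them exactly. Note the confound acts as a *second common factor*
  across raw items of a category; the CFA stage is therefore run on
  confound-residualized items, matching the correct-then-normalize order of
  the motivating design.

What the generator does **not** emulate: spatial autocorrelation of
exposures, non-Gaussian or ordinal symptom scales, missingness mechanisms,
population stratification beyond PC covariates, and realistic genetic
architecture (few loci, one gene per LD block). Passing tests show the
pipeline recovers the planted linear-Gaussian structure at the stated
sample sizes; they do not certify behavior under those unmodeled features.

## QC and latent category construction

* `mad_filter` masks values more than k (default 4) raw median absolute
  deviations from the feature median; MAD is unscaled by default
  (`scaled=True` applies 1.4826). Masking is per value; downstream stages
  use complete cases. Single-pass semantics: a second pass could mask more.
* `near_zero_variance` mirrors the conventional screen: flag when the
  frequency ratio of the two most common values ≥ 19 (95/5) and percent
  distinct ≤ 10%.
* `fit_cfa_one_factor` minimizes F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p over
  loadings and uniquenesses with the factor variance fixed at 1
  (identification) and the sign fixed so loadings sum ≥ 0; L-BFGS-B with
  analytic gradients, uniquenesses floored at 1e−6 (Heywood cases flagged,
  not fatal). χ² = (n−1)·F_ML; the independence model is the baseline for
  CFI/TLI; SRMR is the RMS of standardized residuals over the lower
  triangle including the diagonal. Three items are just-identified (df=0):
  the fit is exact and indices are reported as undefined, which the pruning
  loop treats as "criteria not met".
* `cfa_item_prune` iterates fit → test (TLI>0.95, CFI>0.95, RMSEA<0.06,
  SRMR<0.08) → drop the smallest-|loading| item, down to `min_items`. A
  genuinely independent extra item cannot be flagged by fit (a zero-loading
  item is consistent with the one-factor model); the pruning tests use an
  item correlated with one indicator's uniqueness, which does violate the
  structure and is removed first.
* `build_categories` scores each multi-item category out-of-fold: ten folds,
  prune+fit on nine, regression-method scores f = λᵀΣ⁻¹(x − x̄_train) on the
  held-out fold. No participant is ever scored by a model that saw them.

## The stability-selected sCCA protocol

For preprocessed views X (categories) and Y (symptoms):

1. 90/10 train/test split (seeded).
2. 100 resamples of half the training rows, drawn without replacement
   (a with-replacement option exists).
3. On each resample, rank-one sparse CCA by penalized matrix decomposition:
   alternating soft-thresholded updates of w_x, w_y with per-view L1 bound
   c = s·√p, s = 0.5. The threshold achieving the bound is computed exactly
   (per-segment quadratic over the sorted magnitudes) rather than by
   bisection. Initialization is the leading singular pair of the
   cross-covariance: deterministic.
4. Features with non-zero weight in ≥ 90% of resamples form the stable set
   (85% in the three-block analysis). Empty stable sets are a typed
   "no stable signal" outcome that terminates the mode search.
5. Refit on the stable sets with the sparsity constraint released. The
   default refit (`refit_method="covariance"`) is the rank-one
   cross-covariance fit (the sparse algorithm at s=1); a whitened
   first-canonical-pair refit (`"cca"`, ridge `refit_ridge`) is available.
   The covariance refit is preferred because the whitened in-sample optimum
   is nearly flat when the stable set is internally correlated: its weights
   wander far from the population optimum at moderate n, and deflating with
   imprecise weights leaves a correlated residue that re-surfaces as
   spurious extra modes.
6. Train significance: Y's rows are permuted and steps 2–5 re-run, 1,000
   times at production scale (tests use 99–199); one-sided
   p = (1 + #{r_perm ≥ r_obs})/(1 + B); permutations with empty stable sets
   contribute r_perm = 0.
7. The trained weights are applied to the held-out split (r_test).
8. Test significance: test rows of the symptom view are shuffled under
   *fixed* weights, same one-sided p.

Significant modes are removed by **orthogonalized projection deflation**:
M′ = (I − uuᵀ/uᵀu) M (I − wwᵀ) with u = Mw, applied to both views, train
and test. The column projection satisfies the projection-deflation contract
M′w = 0; the row projection additionally makes every later training variate
exactly uncorrelated with the extracted one (plain column-space projection
does not decorrelate variates — the known gap between projection and
Hotelling deflation). Benjamini–Hochberg FDR is applied across the test
p-values of the extracted modes.

Cross-loadings are Pearson correlations of each category with each mode's
symptom variate; EV = 100·ρ², and the FEV of symptom group k attributed to
profile m is the share of k's summed EV over m's stable set, normalized to
100% across profiles.

Known desk-scale behavior, documented rather than hidden: stability
selection has a false-pass floor because a noise feature's fixed in-sample
correlation with the latent persists across resamples; at n = 5,000 a
handful of false features can pass the 90% threshold (they carry near-zero
refit weight and do not harm recovery). At cohort scale (n > 10⁵) the
effect vanishes with the sampling error.

## Three-block msCCA

`sgcca_rank1` maximizes Σ_{j<k} d_jk·cov(X_j w_j, X_k w_k) over unit-norm,
L1-bounded block weights by cyclic soft-thresholded updates (Horst scheme,
fully connected design by default); each update solves its block's
subproblem exactly, so the objective is monotone — asserted at run time.
Initialization is a feasible sparse projection of each block's leading
principal direction (deterministic power iteration). The surrounding
protocol matches the two-view pipeline with an 85% stability threshold; the
permutation test shuffles the symptom block's rows and re-runs selection
and refit, gating mode significance on the design-weighted objective (the
per-pair permutation p-values are reported from the same null; note that a
symptom-block permutation is an exchangeability null for the
symptom-involving pairs, while for the env–brain pair it is a
selection-stability null). Intracranial volume is included among the brain
confounds upstream.

## Genetics

* `gwas_linear` fits, per variant, OLS of the symptom variate on
  [1, dosage, covariates] via Frisch–Waugh–Lovell (y and all dosages
  residualized on the shared covariates once), which is algebraically
  identical to the per-variant solve including the t-test with n − k df.
* QC keeps MAF ≥ 0.001 and imputation INFO ≥ 0.3.
* `clump` is greedy: visit variants by ascending p (ties by position, then
  ID); an index removes unassigned variants on the same chromosome within
  250 kb (inclusive) with dosage r² > 0.5; `p1` = 1 admits every variant as
  a potential index.
* `gene_score` is the weighted allele score Σ dosage × GWAS β over a gene's
  index variants (effect-allele orientation; dosages, not hard calls).
* `stratified_correlation_test` splits at the score median (tertiles
  optional) and compares the environment–symptom correlation between strata
  by Fisher's z.

## Moderated mediation (Model 59)

Two OLS equations on mean-centered X, W, M (products formed after
centering): M on {X, W, XW, covariates}; Y on {X, W, XW, M, MW,
covariates}. Conditional indirect effect (a1 + a3·w)(b1 + b2·w) and direct
effect c′ + c3·w are evaluated at the 16th/50th/84th percentiles of the
centered moderator (low/medium/high genetic risk). Inference: B resamples
of participants with replacement (default 5,000; tests use 999), refit,
bias-corrected percentile CI (BC, no acceleration): z0 = Φ⁻¹(#{θ* < θ̂}/B),
bounds at bootstrap quantiles Φ(2z0 ± z_{α/2}). Singular resamples are
redrawn and counted. A constant moderator degrades gracefully to simple
mediation (interaction columns dropped, their coefficients reported as 0).
The explained mediation effect is implemented as proportion mediated at the
median moderator, EME = 100·indirect/(indirect + direct), undefined (NaN,
flagged) when |total| < 1e−6; the formula is exposed in the result and
swappable.

## Orchestration and reproducibility

`full_pipeline` replays the chain on one cohort with the original split
bookkeeping: a non-imaging subset carries sCCA and GWAS; an imaging subset
carries msCCA and mediation (`imaging_fraction`, default 0.4). One run seed
fans out to per-stage seeds through a fixed affine counter scheme; the
manifest records a config hash (excluding the output directory), per-stage
seeds, output hashes and timings, and deterministic stages are bit-identical
across reruns.

## Problem sizes used by the test suite

The suite exercises the full protocol at n = 5,000 with 53 environment
categories and 21 symptoms (100 resamples, 199 permutations), permutation
calibration on 200 null datasets of n = 1,000 (99 permutations each, 10
resamples, p = 8, q = 4, s = 0.8, τ = 0.6 — chosen so the observed run
almost always yields a stable set; datasets without one count as
non-rejections), bootstrap coverage on 200 replicates of n = 2,000 with
B = 999, and GWAS/clumping oracles on hundreds of small random instances.
Production-scale settings (1,000–10,000 permutations, B = 5,000) are the
library defaults.

## Known limitations

* The permutation gate inherits the conservative r_perm = 0 convention for
  empty-selection permutations; when the observed run *does* select, this
  makes the test sensitive to any selectable structure, which is why clean
  deflation (covariance refit + orthogonalized projection) matters.
* One-factor CFA only; no ordinal estimators or measurement-invariance
  testing.
* The msCCA permutation null for the env–brain pair conditions on
  re-selection rather than full exchangeability (see above).
* EME is one of several possible summaries of moderated mediation; the
  implemented definition is stated in the result metadata.
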