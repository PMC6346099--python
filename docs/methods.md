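# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical conventions and the design choices behind `pcbscan`.

## The mixed model and its fitting

Each transcript is modelled as

    y = X beta + Z u + e,   u ~ N(0, sigma2_u I_B),   e ~ N(0, sigma2_e I_n)

with one random intercept per scan-date batch (B batches). Writing
`lambda = sigma2_u / sigma2_e`, the marginal covariance is
`sigma2_e (I + lambda Z Z')`. For fixed lambda, the GLS estimate of `beta`
and the ML estimate of `sigma2_e` are closed-form, so the log-likelihood is
profiled to a one-dimensional function of lambda. The implementation never
forms the n × n covariance: whitening within batch a,
`y* = y - theta_a * mean_a(y)` with `theta_a = 1 - 1/sqrt(1 + n_a lambda)`,
reduces every needed quantity to per-batch sums, which lets a whole
transcriptome (thousands of responses sharing one design) be profiled with
batched matrix operations.

The lambda search evaluates a 35-point grid over {0} ∪ [1e-8, 1e3]
(log-spaced) and refines the bracketing interval with 42 golden-section
iterations on log10(lambda); the lambda = 0 boundary is always admitted as a
final candidate. Fits are by ML, not REML, because the likelihood-ratio
tests compare models with different fixed effects. Against a
direct-covariance grid+refine oracle the profiled optimum agrees to better
than 1e-12 in log-likelihood on n = 50 fixtures; with a single batch the
fitter pins lambda to 0 and reproduces OLS exactly. Responses with variance
below 1e-12 are skipped and logged, and excluded from the FDR denominator.

### Testing and the LRT reference distribution

Each transcript's p-value comes from the likelihood-ratio statistic
`LR = 2 (ll_full - ll_reduced)`, floored at zero. Two reference
distributions are available on `ScanSpec.lrt_reference`:

- `"f"` (default): invert the exact algebraic identity that holds when the
  batch variance vanishes, `LR = n log(1 + df·F / (n - p))`, and refer the
  implied F statistic to F(df, n - p), where p counts the full model's fixed
  effects. This is exact at lambda = 0 and a very good approximation
  otherwise; at desk scale (n = 300, ~15 fixed effects) it keeps the null
  type-I error at 5.1% ± binomial noise.
- `"chisq"`: the large-sample chi-square(df) reference, kept for
  asymptotic use and exposed through `lrt_nested` for generic nested model
  comparison. At n = 300 with 15 fixed effects it is visibly
  anticonservative (~5.7–6% at the nominal 5%), which is why it is not the
  scan default.

A Wald z-test on the coefficient (`test="wald"`) is provided as a
sensitivity analysis; it ranks transcripts essentially identically to the
LRT.

BH correction is applied within each scan (one stratum × congener ×
cell-type configuration), matching how per-scan hit counts are usually
reported; a lenient preset (`ScanSpec.lenient()`, FDR 0.2) is included. BH
q-values use the step-up cumulative-minimum form; missing p-values are
excluded from the correction and returned as missing.

## Exposure handling and collinearity

Serum PCB concentrations are right-skewed and strongly co-accumulating, so
the scans transform the exposure (default log then z-score; `none`, `log`,
`zscore` also available). Z-scoring makes scan p-values invariant to affine
rescaling of the raw exposure. The VIF screen (threshold 4, iterative
worst-first removal with recomputation) encodes the standard conclusion for
such data: the six congeners cannot share a model (one congener per scan),
and granulocytes — the dominant cell fraction, structurally collinear with
the remaining fractions on the simplex — are dropped from the WBC
covariates by default. Categoricals enter VIF and scans as dummy columns
with the first level dropped; generalized (block) VIF is out of scope.

## Power planning

`power_linear_model(u, v, f2, alpha)` is the noncentral-F power of the
linear-model F test with noncentrality `f2 (u + v + 1)`; `f2 = 0` returns
alpha exactly. `f2_for_power` inverts it by bracketed root finding, and
`interaction_effect_for_power` converts the resulting f2 into a raw
interaction coefficient using the realized design (variance of the product
column after residualizing on all other fixed effects). When planting
effects meant to survive BH at level q with a non-null fraction pi1, the
per-test alpha for the power calculation should be the expected BH cutoff
q·pi1, not q itself: an effect with 80% power at alpha = 0.05 has only ~30%
power at the ~0.002 threshold BH actually applies in a 5%-non-null scan,
whereas sizing at alpha = q·pi1 yields ~75–80% post-BH sensitivity with
empirical FDR at or below the nominal level. The planted-effect recovery
checks use this convention.

## Synthetic cohort generator

The generator targets the statistical structure the analysis assumes, not
the magnitudes or noise spectra of any real platform. Defaults (all
overridable via `CohortConfig`):

- **Size and outcome**: 512 subjects, 217 future lymphoma cases / 295
  controls; time to diagnosis truncated-normal, mean 5.96 y, sd 2.85 y,
  bounds [2, 17]. Future cancer type collapses to a single lymphoma label.
- **Exposures**: per-congener log-normal with a shared equicorrelated
  Gaussian copula (pairwise r = 0.6) on the log scale; log-SD 0.5 for all
  congeners; arbitrary mass/volume units. Females receive a +0.3 log-SD
  shift on congeners 118/156/170/180, reproducing the qualitative
  female-elevated pattern on those congeners (≈92% t-test detection per
  congener at n = 512, ~5% on the unshifted ones).
- **Cell fractions**: Dirichlet with mean (NK .07, B .05, Mono .08,
  Gran .60, CD8T .08, CD4T .12) and precision 60 — realistic adult blood
  composition with realistic person-to-person spread.
- **Confounders**: age ~ N(53.3, 7.8²) (the cohort's reported mean age for
  females, used for both sexes), BMI ~ N(26, 4²), smoking never/former/
  current at 50/30/20%, two cohort labels at 50/50.
- **Batches**: 20 scan-date batches by default (at least 2 subjects per
  used level), batch variance sigma2_u = 0.2 · sigma2_e unless set
  otherwise.
- **Expression**: linear predictor from `SimulationTruth` (intercepts,
  per-congener main effects, per-cell-type effects, congener × cell-type
  interaction matrix, confounder effects), using log-z-scored exposures and
  raw fractions; a per-transcript sex mask restricts exposure-driven terms
  to one sex to emulate sex-specific responses; batch intercepts are drawn
  independently per transcript.
- **Methylation fixtures**: a synthetic purified-leukocyte reference
  (Beta(0.5, 0.5) per CpG × cell type, well-conditioned) mixed by the true
  fractions plus Gaussian noise, clipped to [0, 1].

What the generator does **not** emulate: probe-level intensity
distributions, heteroskedastic array noise, correlated transcripts
(co-expression), cohort-specific exposure magnitudes, or methylation array
artifacts. Passing tests therefore demonstrate the statistical machinery
(calibration, FDR control, recovery, exactness of the numerics) under the
assumed model, not robustness to real-data violations of it.

## Preprocessing conventions

- Pixel filter: a probe measurement is kept when its pixel fraction is at
  least the threshold (default 0.75, i.e. 75% coverage exactly is kept).
- kNN imputation (default k = 15): Euclidean distance on mean-centered
  features over pairwise-complete positions, rescaled by sqrt(p/p_obs);
  missing entries become the unweighted mean of the k nearest features
  observed at that position. Observed cells are never altered; ties in
  distance break by stable feature order.
- Quantile normalization: columns are mapped onto the row-means of the
  column-sorted matrix; ties receive the average of the tied positions'
  values (computed via average ranks and linear interpolation). The
  operation is idempotent to 1e-12.
- Default order is filter → impute → normalize. Normalize-before-impute is
  expressible but requires complete data after filtering, since quantile
  normalization refuses missing values by contract.
- A running-median intensity detrend (window 101 features over the average
  intensity ranking) is available as a single-channel stand-in for
  within-array trend correction; it defaults off.

## Deconvolution

Per subject, the estimator solves min ||R f − m||² subject to f ≥ 0 and
sum(f) ≤ 1 (or = 1 with `sum_to_one=True`), then renormalizes to the
simplex. With six cell types the convex program is solved exactly by
enumerating KKT active sets (every subset of zeroed coordinates × sum
constraint active/inactive; 128 small equality-constrained solves), keeping
the feasible candidate with minimal objective — deterministic and exact to
linear-algebra precision, so noiseless mixtures are recovered to ~1e-15.
The ≤ 1-then-renormalize convention is the default dialect; both behaviors
are exposed because the two conventions differ only through noise.
Reference construction and CpG selection are taken as given.

## Downstream stages

- `stratified_scan_counts` runs the interaction scan per (sex × case
  status × congener × cell type) cell, reporting significant counts and the
  control/case overlap; strata under 30 subjects (configurable) return NA
  with a logged reason.
- `exposure_sex_ttest` is Welch's t on the scan's exposure transform.
- Batch correction for the time-to-diagnosis stage subtracts the
  empirical-Bayes batch predictions (BLUPs)
  `u_a = lambda n_a / (1 + lambda n_a) · mean residual of batch a` from the
  confounder-only LMM fit. Pearson correlation is the default
  (`method="spearman"` available).
- The differential-expression signature uses Welch's t and log2 fold
  changes on log2-scale expression (|FC| ≥ 1.5, BH q ≤ 0.05, then the top
  and bottom 5% of fold change). Welch's t stands in for moderated
  empirical-Bayes tests, which need array-scale gene counts to estimate a
  variance prior.
- Over-representation is the exact hypergeometric upper tail against a
  user-supplied background and GMT pathway collections, BH-corrected across
  pathways.

## Problem sizes used in the checks

Null calibration runs 2000 transcripts at n = 300 with 10 batches;
planted-effect recovery 2000 transcripts at n = 500; variance recovery 40
batches × 25 subjects over 50 seeds; deconvolution 200 CpGs × 100 subjects
at noise sd 0.02; the sex-pattern check 100 cohorts of 512. These sizes
were chosen so the full statistical battery runs in minutes on one CPU
while keeping Monte-Carlo error well below the tolerances being checked.

## Known limitations

- One random intercept only; no nested (cohort/scan-date) or crossed random
  effects, no kinship structure, no REML.
- Transcripts are modelled and simulated independently; no variance
  moderation across transcripts and no co-expression.
- The chi-square LRT reference is anticonservative at small n (use the
  default F calibration).
- Exposure measurement error and lipid standardization of serum
  concentrations are not modelled; the exposure transform is the only
  handle.
- External pathway/known-gene resources are user-supplied files; no online
  services are queried.
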