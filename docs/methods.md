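# Methods

## Scope and model

`gestclock` implements the downstream analysis of gestational epigenetic
age: clock application and accuracy metrics, age-acceleration
residualization, bootstrapped elastic-net variable selection, cross-cohort
replication and cross-tissue concordance. Array preprocessing (QC,
normalization, batch correction), cell-type deconvolution and ancestry
estimation are upstream: beta matrices, cell proportions and ancestry
components are consumed as inputs.

## Clock application

A clock is `c0 + Σ w_j β_j` over its CpG set; a days-unit clock is divided
by 7 exactly (no rounding). Missing-CpG policy:

* `exclude` (default): clock CpGs absent from the matrix are dropped from
  the sum with **no reweighting** of the remaining coefficients, and
  `n_cpgs_missing` is reported per estimate. This mirrors how published
  gestational clocks are applied on arrays lacking part of their CpG set.
* `strict`: any absent CpG raises, for validation runs.

Samples with missing values among the retained CpGs are dropped with a
logged warning. **MAD** here is the median absolute difference
median|DNAm GA − GA| — not the median absolute deviation from the median.
SDs use the n−1 denominator throughout.

## EAAR

Ordinary least squares of DNAm GA on GA, the tissue's cell proportions and
two ancestry components, with intercept; residuals stay in weeks. Cell
proportions are compositional, so the alphabetically last cell-type column
is dropped as reference — a deterministic, documented choice; the fitted
column space, hence the residuals, are invariant to it (unit-tested).
Complete-case analysis per tissue; for CVS the GA at sampling is used, for
term tissues the GA at birth. Rank-deficient designs raise with the names
of the collinear columns (QR diagnostic). z-standardization of predictors
and outcome happens only at the entry of the selection stage, keeping EAAR
interpretable in weeks for cross-tissue summaries.

## VIP selection

Per bootstrap resample (n draws with replacement; CV fold assignment
redrawn per bootstrap and shared across the alpha grid):

1. per alpha ∈ {0, 0.1, …, 1}: a 100-value lambda path, log-spaced from
   the smallest all-zero lambda (max|X'y|/(n·alpha)) down to 1e−4 of it;
   alpha = 0 anchors its path at alpha = 0.001 since the ridge lambda_max
   diverges. Fits are on centered data (equivalent to an unpenalized
   intercept); pure ridge uses the closed-form normal-equation solution.
2. 10-fold CV MSE (cvm) per (alpha, lambda), folds centered on their
   training part; *nzero* of a grid point is the non-zero count of the fit
   on the **full** bootstrap resample.
3. per (bootstrap, nzero), only the minimum-cvm grid point is retained
   (first minimum in alpha-ascending, lambda-descending scan order).

X and y are standardized **once** on the full complete-case data, not
re-standardized per resample, so coefficients are comparable across
bootstraps for the median/CI aggregation. VIP of a variable at a given
nzero is the percentage of the bootstraps *contributing* at that nzero
whose best model has it non-zero; nzero values contributed by fewer than
50% of bootstraps are excluded from the elbow curve (reported separately).

**Elbow.** Both axes of the (nzero, median cvm) curve are min-max scaled
to [0, 1]; the chosen size is the interior point with the largest
perpendicular distance **below** the chord from the first to the last
point. The signed (below-chord) distance matters: the rule's purpose is to
find the position of most-decreasing cvm, and on a flat noise curve the
absolute distance would elect bumps *above* the chord, which are never an
elbow. Ties break toward the smallest nzero (parsimony). Curves shorter
than 3 points or with non-decreasing cvm fall back to the argmin of median
cvm; curves with no interior point below the chord degenerate to the
smallest interior nzero; all fallbacks are flagged in the result.

**Stability and summaries.** Stable = VIP strictly greater than 75%
(configurable) at the chosen nzero. Coefficient medians and 95% CIs
(linear-interpolation percentiles) are taken across the bootstraps where
the variable was non-zero at that size; the exported prediction vector
holds the medians of the stable variables and zero elsewhere. Elastic-net
medians carry the penalty's soft-threshold bias — at these study
conditions (n = 400, 13 predictors) roughly 0.07–0.10 on the standardized
scale — which is intrinsic to summarizing penalized fits, not an
estimation defect.

The inner path solver is a numba-compiled cyclic coordinate descent with
covariance (Gram) updates and warm starts, in the glmnet
parameterization; it is cross-checked against an independent elastic-net
implementation in the unit tests. Compilation makes the ~10^5 path fits
of a full bootstrap study feasible on one CPU.

## Replication and cross-tissue statistics

`predict_external` applies a named coefficient vector to an external
cohort's z-standardized predictors with no intercept (both sides
standardized). The one-tailed Pearson p uses the exact t-transform
`t = r·sqrt((n−2)/(1−r²))`, upper tail, n−2 df.

Cross-tissue concordance reports Pearson r (two-sided p) for DNAm GA and
EAAR between matched individuals, per-tissue EAAR means/SDs, and a paired
location test on the EAAR differences. The parametric/non-parametric gate
is Shapiro–Wilk on the differences at α = 0.05 — Student's paired t if
normality is not rejected, Wilcoxon signed-rank (zero differences
dropped) otherwise; both test results are always emitted so the gate is
auditable. Identically zero differences are reported as "degenerate"
(no difference). Matching is by individual id; duplicate samples per
(individual, tissue) raise.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with all planted quantities in a `SyntheticTruth` oracle:

* **GA**: truncated normal by rejection; term birth mean 39.9, SD 1.5,
  truncated [33, 43] weeks; CVS sampling mean 12.8, SD 0.8, [10, 15].
* **Predictors**: 13 birth/pregnancy variables (alcohol use optional
  14th) from a latent Gaussian with a modest, realistic correlation
  structure (anthropometric, obstetric and metabolic clusters); binaries
  by prevalence-matched thresholding, continuous by affine mapping to
  their published-style means/SDs.
* **Acceleration**: a_i = Σ_k γ_k x_ik(std) + ε_i with γ in weeks per SD
  and ε ~ N(0, σ_a²), σ_a = 0.7 weeks by default. Across tissues ε is
  multivariate normal with pairwise correlation ρ, so the planted
  cross-tissue correlation of the total acceleration equals ρ exactly
  when γ = 0 (the cross-tissue scenarios therefore set γ = 0).
* **Cell confound**: proportions are Dirichlet per tissue; δ (default 1
  week per SD) times the standardized first proportion (nucleated red
  blood cells) enters the target age, so the EAAR cell adjustment is
  genuinely exercised.
* **Betas**: rank-one around the clock: β_ij = m_j + v_j(t_i − c0 − w·m)
  + η_ij with v = w/‖w‖² (so w·v = 1), base profile m_j ~ U(0.2, 0.8)
  minimally clamped so all noise-free betas lie in [0.05, 0.95]
  (incompatible clock/target ranges raise), and η ~ N(0, σ_β²) with
  σ_β = 0.02, final clip to [0, 1] with the clipped fraction reported
  (< 1% required at defaults). The rank-one construction guarantees the
  clock recovers the planted target age *exactly* in the noise-free
  limit, which makes clock application analytically testable.
* **Toy clocks**: weights of magnitude U(0.4, 1.0) with random signs;
  the intercept maps a flat 0.5 profile to the tissue's GA center. Each
  tissue gets its own clock, as in practice.

Shipped scenarios: `null` (all γ = 0), `cordblood_like` (five planted
effects with the sign pattern reported for term cord blood: smoking,
mental disorders, aided delivery and birth length accelerate, female sex
decelerates), `cordblood_independent` (the same effect budget on a
latently unrelated predictor set, for transfer-null experiments) and
`crosstissue_null` (two tissues, ρ configurable). The cordblood_like
effects (0.22–0.26 weeks/SD, standardized ≈ 0.25–0.29) sit near the
smallest size the selection should still detect reliably at n = 400 while
remaining recoverable by the (shrinkage-biased) coefficient medians —
both a realistic epidemiological magnitude and the regime the recovery
analyses are designed for.

**What the generator does not emulate**: probe-level measurement error
structure, normalization and batch artifacts, genuine cell-type reference
error, non-linear GA effects, missingness patterns. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the assumed model, not robustness to array-data pathologies.

## Numerical choices

* Coordinate descent: tolerance 1e−7 on the maximum coefficient change
  per sweep, max 10 000 sweeps, exact zeros from the soft threshold.
* Elbow tie tolerance 1e−12 on normalized distances.
* Percentiles: linear interpolation between order statistics
  (`numpy.percentile` default).
* All RNG flows through `numpy.random.SeedSequence` spawning, so every
  stage is byte-reproducible from (config, seed); seeds derived for
  sub-streams stay below 2³¹.
* Problem sizes in the test suite and acceptance script: selection
  studies at n = 400, B = 200, 50 replicates (tests) or 20 replicates
  (acceptance script); transfer at B = 100; cross-tissue at n = 350.
  B = 1000 — the convention for a real study — is the library default.

## Known limitations

* The min-cvm-per-(bootstrap, nzero) grouping inherits a selection bias:
  group sizes differ, so measured cvm is biased slightly downward for
  sizes with many candidate (alpha, lambda) points. Under a global null
  the median-cvm curve is therefore flat-with-dips rather than
  increasing; the below-chord elbow plus the strict 75% rule keep false
  stability rare, but a single "lucky" predictor of the original sample
  can occasionally be stably re-selected at nzero = 1–2 — bootstrapping
  cannot model the sampling variability of the original draw.
* Coefficient medians are shrunk by the penalty (see above); they are
  selection summaries, not unbiased effect estimates.
* One-tailed replication assumes the transferred score is oriented
  (positive association expected); a sign-flipped discovery would need
  the orientation fixed upstream.
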