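# Methods

## Problem setting

The package analyzes a cohort with paired measurements of plasma LDL
cholesterol (LDL-C, mg/dL), small dense LDL concentration (sdLDL; reported
in the source assay's units — the magnitudes are consistent with NMR
particle concentrations rather than mg/dL, so the generator and the models
treat the units as opaque), demographic covariates, and whole-blood bulk
RNA-seq counts.  The scientific question is whether sdLDL *mediates* the
association between LDL-C and gene expression: LDL-C raises sdLDL
(standardized slope ≈ Pearson correlation ≈ 0.4), and sdLDL may in turn be
the proximal correlate of expression changes.

## Differential expression model

For each gene g and sample i with count y_gi:

- y_gi ~ NB(μ_gi, φ_g) with Var = μ + φμ², log link,
- log μ_gi = log(Ñ_i) + x_iᵀβ_g, where Ñ_i is the TMM-effective library
  size used as an offset,
- x_i contains an intercept, the tertile-group indicator (1 = upper tertile
  of the phenotype, samples in the middle tertile are excluded), standardized
  age, a male indicator, and education dummies against a `<=high_school`
  reference with "not available" kept as its own level (dropping missing
  education would discard a large fraction of a typical cohort),
- optionally a standardized continuous mediator column (sdLDL) for the
  adjusted fit.

Tertile cutpoints are the empirical 1/3 and 2/3 quantiles
(linear-interpolation definition); ties at a cutpoint fall to the lower bin
for determinism.  The contrast focuses on distribution extremes, which
amplifies signal at the cost of discarding a third of the cohort.

**Fitting.**  All genes share one design matrix, so the IRLS updates are
vectorized across genes: per iteration the weighted normal equations
XᵀW_gX β_g = XᵀW_g z_g are assembled with einsum and solved as a batched
p×p system.  Convergence is a relative deviance change < 1e-8, at most 100
iterations; φ = 0 degrades to Poisson.  Per-gene fits agree with statsmodels
GLM (Poisson and NegativeBinomial(alpha)) to ≈1e-5, which the tests verify.

**Dispersion.**  Per-gene φ is estimated by maximizing the Cox–Reid adjusted
profile likelihood APL(φ) = ℓ(β̂(φ); φ) − ½ log det(XᵀWX) over a 29-point
grid of log10 φ in [−6, 1] with quadratic refinement at the maximum, then
shrunk toward a mean–dispersion trend (running median of the per-gene
maximizers ordered by average log2 CPM, window ≈ 10% of genes) with a prior
weight of 10 degrees of freedom:
log φ_shrunk = (d·log φ̂ + d₀·log φ_trend)/(d + d₀), d = n − p, d₀ = 10.
With hundreds of residual degrees of freedom the shrinkage is mild, which is
the intended behavior at these sample sizes.  Genes with fewer positive
counts than design columns take the trend value directly.  This is
deliberately edgeR-*like*; exact numerical equality with edgeR is not a goal.

**Testing.**  The group coefficient is tested by LRT against the model
without the group column, both fitted at the gene's shrunken dispersion;
the statistic is referred to χ²(1).  BH adjustment runs across all converged
genes; significance is FDR ≤ 0.05.  logFC is reported in log2 (natural-log
coefficients divided by ln 2).

## Normalization

TMM scaling factors follow the standard trimmed-mean-of-M-values recipe:
reference sample = the one whose upper-quartile count fraction is closest to
the mean fraction (ties to the lowest column index, making the choice
order-independent); per sample, M/A arrays over genes positive in both
sample and reference; two-sided trimming of 30% on M and 5% on A;
factor = 2^(precision-weighted mean M) with delta-method binomial weights
(an unweighted variant is available); factors rescaled to geometric mean 1.
A sample pair retaining fewer than 10 genes after trimming gets factor 1
with a warning.  One test cross-checks the factors against
`edgeR::calcNormFactors` to 2%.

The low-expression filter retains genes with CPM ≥ 1 (raw library sizes,
factors of one) in ≥ 3 samples, applied *before* TMM as in the standard
count workflow; both thresholds and the ordering are configurable.

## Mediation screen

Three conditions plus a concordance requirement, all deterministic given the
three DE fits:

1. LDL-C contrast FDR ≤ α (default 0.05),
2. sdLDL contrast FDR ≤ α,
   with sign(logFC_LDL) = sign(logFC_sdLDL),
3. |logFC_LDL, adjusted for sdLDL| < |logFC_LDL| (strict attenuation, no
   minimum-attenuation threshold).

The adjusted model adds sdLDL as a standardized continuous covariate (not
tertile-coded) — adding the measured value is the plain reading of
"incorporating the mediator as a covariate"; it is fitted lazily, only for
genes passing 1–2 with concordance.  The mediator covariate is standardized
within the tertile-included samples.  One covariate list (default age, sex,
education) is used for all three fits.

For mediated genes, proportion mediated PM = 100·(1 − logFC_adj/logFC_base)
clamped to [0, 100]; undefined when the base logFC is zero.  The screen
itself attaches no inference to PM — it is a deterministic effect-size
decomposition, not a causal estimand, and direct-path genes whose phenotype
is merely correlated with the mediator can pass it (see Limitations).  An
optional percentile bootstrap (`bootstrap_proportion_mediated`, `mediate
--bootstrap B`) resamples samples, refits the base and adjusted models at
fixed dispersions and TMM factors, and reports a PM interval; it defaults
off because the screen's definition is point-estimate based.

## Sex stratification

Each stratum is treated as a fresh cohort: tertile cutpoints and TMM factors
are recomputed within the stratum (pooled cutpoints would unbalance the
stratum group sizes), sex leaves the covariate list, and BH runs within the
supplied gene subset per stratum (the screen is applied to a pre-identified
mediated set, not transcriptome-wide).  TMM factors use all genes of the
supplied matrix even though the screen covers the subset.  Education dummies
that become degenerate inside a stratum are dropped with a warning.  Each
stratum must contain at least three samples per design column.

## Enrichment

Upper-tail hypergeometric p-values P(X ≥ k) per gene set, with
K = |set ∩ universe|, n = |query|, N = |universe|.  The universe defaults to
the genes tested in the DE stage (standard over-representation practice),
not the genome.  Raw p-values are thresholded (≤ 0.05) together with a
minimum overlap of 2; a BH column is emitted for reference but not used for
filtering, matching the common reporting convention for small candidate
lists.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline is designed
for, and are fixed:

| parameter | default | meaning |
|---|---|---|
| n_samples / n_genes | 400 / 2,000 | cohort grid, stable tertile DE in minutes |
| LDL-C | mean 105, SD 33 mg/dL | zero-truncated normal |
| sdLDL | mean 477, SD 333, corr 0.40 | truncated linear-Gaussian in z(LDL-C) |
| age | mean 48, SD 12 yr | zero-truncated normal |
| sex | 69% female | Bernoulli |
| education | 6/15/17/20/42% | includes "not_available" as a level |
| lipid medication | 10% | recorded, not used as a default covariate |
| gene classes | 90% null, 5% direct-only, 5% mediated | "mixed" fraction defaults to 0 |
| planted effects | sign·(0.2 + \|N(0, 0.4)\|) per SD, natural log | strong-signal regime |
| covariate effects | age N(0, 0.02), sex N(0, 0.05) | small nuisance effects |
| dispersion | Gamma(2, 0.05), mean 0.1 | per-gene NB dispersion |
| library sizes | log-normal, median 2e6, log-SD 0.3 | per-sample depth |

**sdLDL calibration.**  sdLDL is drawn from the conditional normal
y | z ~ N(μ + σρz, σ²(1−ρ²)) truncated to (0, ∞), with z the standardized
LDL-C.  Truncating a normal with mean 477 and SD 333 at zero removes ≈7.6%
of its mass, which would bias the observed moments and shrink the observed
correlation well below the target, so the latent (μ, σ, ρ) are solved
numerically (Gauss–Hermite quadrature over z, hybrid root finding) such that
the *observed truncated* mean, SD and Pearson correlation equal the
configured values.  The calibration is deterministic, independent of the
seed, and accurate to ≈1e-6; at n = 100,000 the empirical correlation lands
within Monte-Carlo error (±0.005) of the 0.40 target.

**Effect floors.**  Planted effect magnitudes are bounded below (default
0.2 natural-log units per phenotype SD) so that recovery simulations measure
the screen's logic rather than raw detection power at the margin.  Real
cohort effects are typically weaker; sensitivity numbers from the recovery
tests therefore characterize the strong-signal regime, not field
performance.

**Ground truth.**  On standardized phenotypes the total LDL-C effect on a
gene's log-mean decomposes as β_direct + β_mediator·a (a = standardized
sdLDL-on-LDL-C slope = the target correlation), so the true proportion
mediated has the closed form 100·β_mediator·a/(β_direct + β_mediator·a),
clamped like its estimate and undefined at zero total effect.  Fully
mediated genes (β_direct = 0) have true PM = 100.

**What the generator does not emulate:** gene–gene correlation networks
(counts are conditionally independent given the phenotypes), batch or
technical covariates, outlier samples, exposure–mediator interactions, and
any feedback from expression to lipids.  Passing recovery tests therefore
demonstrates correctness of the screen under its own assumptions, not
robustness to those real-data features.

A single user seed fans out into independent per-stage substreams
(phenotypes, counts), so identical seeds give bit-identical cohorts and the
pipeline is fully deterministic end to end.

## Numerical choices and degenerate inputs

- Linear predictors are clipped to ±50 and fitted means floored at 1e-10
  inside IRLS; the LRT statistic is floored at 0 (full nests reduced).
- Non-converged or all-zero genes keep their rows but carry NaN p-values and
  are excluded from BH, with a warning reporting the count.
- Dispersion search bounds: log10 φ ∈ [−6, 1]; constant-count genes land at
  the lower bound.
- Tertile assignment requires ≥ 3 finite values and ≥ 2 distinct values;
  constant covariates on the included samples raise; rank-deficient designs
  raise with the collinear columns named.
- p-values entering BH must lie in (0, 1]; chi-square p-values are clipped
  away from zero at the smallest positive double.

## Validation strategy

- **Oracle equivalence**: BH against an explicit sort/scale/cummin oracle
  (1,000 random vectors); hypergeometric tails against exact
  binomial-coefficient rationals (1,000 instances) and exhaustive
  enumeration of all C(N, n) draws for N ≤ 12; single-gene GLM fits against
  statsmodels; TMM against edgeR.
- **Type-I error**: an all-null 2,000-gene, 400-sample cohort gives an LRT
  rejection fraction at 0.05 inside [0.035, 0.065] and passes a KS
  uniformity check at α = 0.01.
- **Recovery**: three default-calibration cohorts (100 planted mediated
  genes each) give ≥ 80% sensitivity for the planted mediated class and
  Spearman ≥ 0.6 between estimated and true PM among detections; with the
  mediator simulated independent of LDL-C, mediated calls fall to ≤ 1% of
  tested genes.
- **Accounting identities**: mediated ⊆ concordant ⊆ (significant in both
  contrasts); the sex classification partitions its input set.

Problem sizes in the test suite (300–2,000 genes, 200–600 samples, three
recovery seeds) were chosen as the smallest grids at which the tertile DE
and the screen are statistically stable.

## Known limitations

- The screen is associational: a gene with a purely direct LDL-C effect
  can satisfy all three conditions because the mediator is correlated with
  the exposure (classic Baron–Kenny confounding); the recovery tests show
  such genes enter the detected set with intermediate estimated PM.
- Strict attenuation with no threshold means negligible attenuations count;
  a configurable minimum-attenuation option exists but defaults off to match
  the screen's definition.
- χ²(1) reference for the LRT and plug-in shrunken dispersions are
  asymptotic devices; they are well calibrated at tertile-group sizes ≥ ~50
  (verified by simulation) but not guaranteed for small strata.
- PM is a ratio of estimates and is noisy when the base logFC is small;
  values are clamped rather than error-propagated.
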