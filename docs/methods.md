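# Methods

This note records the statistical model behind `scale-leveler`, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Preprocessing

All computation happens on the offset log scale `g = log2(x + c)`.

* **Offset `c` (default 0.25, dimensionless raw-count units).** The
  offset keeps unexpressed genes finite. If quantification rounds true
  levels to integers, levels in [0, 0.5) are reported as 0; assuming
  those small levels are roughly uniform, their mean is 0.25. The
  price of the offset is an additive log distortion whose first-order
  size is `c/(bX)` for a gene with true level `X` and multiplicative
  bias `b` (`offset_distortion_bound`); at the filter edge `X = 8` it
  is 1/32, about 3%.
* **Mean-expression filter (default threshold 3.0 log2 units, i.e.
  raw level 8).** Genes with across-sample mean at or below the
  threshold are dropped once, before any correction, and the filter is
  not recomputed afterwards. Filtering bounds the offset distortion
  and avoids the noisiest strata.
* **No Z-score standardization before correction.** The bias acts on
  a gene according to its mean expression level, not its standard
  deviation; dividing each gene by its own sd scrambles the bias so it
  can no longer be estimated. Standardization enters only inside the
  *t* statistics, after correction. No outlier trimming is applied.

## Bias detection

Genes are sorted by mean expression (ties broken by gene id for
reproducibility) and divided into ⌊N/B⌋ consecutive blocks of B genes;
the trailing remainder is dropped rather than folded into a short
block. Per-sample block averages, centered across samples within each
block, form the diagnostic profile: block averaging leaves a smooth
systematic bias intact while shrinking independent per-gene noise by
1/√B. The same profile computed over a seeded random gene order
separates expression-level-dependent bias (trends in the sorted
profile) from overall normalization shifts (flat offsets in the
unsorted profile).

Supporting diagnostics: a windowed profile of per-gene sd (or
variance) along the sorted order, with non-overlapping windows by
default (window 800) and a centered moving average behind a flag; and
a d'Agostino-omnibus normality sweep, per gene across samples or
across disjoint random groups of samples (group means emulate the
averaging inside two-population statistics; disjoint groups rather
than bootstrap resamples keep per-gene observations independent, so a
seed is required). Sample variances use the unbiased (M−1)
denominator throughout.

## Corrections

Three per-sample corrections on the log scale, in increasing order of
expressiveness (none of them touches raw counts):

1. **Shift**: subtract the sample's mean deviation from the cohort
   gene-mean profile. Exactly idempotent; equivalent to a per-sample
   multiplicative renormalization of the raw data.
2. **LLT**: model the bias as a polynomial `β_m(ḡ_n)` in the gene's
   cohort mean. Fit by weighted least squares of block-averaged
   deviations on powers of block-averaged means. The weights are
   `1/max(block-averaged across-sample gene variance, 1e-8)`:
   inter-patient expression variation is the dominant error source, so
   inverse variance is the standard choice; the floor guards
   degenerate blocks. The fitted polynomial is evaluated at the
   *fitting-time* gene means stored in the model, so fit/apply form a
   consistent pair; applying a model to a different gene set is
   refused rather than extrapolated silently.
3. **NLT**: model the measurement as a per-sample change of scale
   `G = α_m(g) + ε` with `α_m` polynomial, fitted by *unweighted*
   least squares of block-averaged cohort means on block averages of
   per-sample powers `⟨g^ℓ⟩_K` — averages of powers, not powers of
   averages, which keeps the pointwise application `α̂_m(g_nm)`
   consistent with the block-level fit. The response error mixes
   several sources with no clean variance model, hence no weights.
   No monotonicity constraint is imposed on `α_m`; a warning is logged
   if the fitted polynomial is non-monotone on the observed range.
   The polynomial is applied over each sample's full observed range,
   including the tails beyond the outermost block centers where it
   extrapolates.

**Defaults `L = 3`, `K = 50`.** Degree-3 polynomials capture the
smooth warps seen in cohort data; higher degrees give negligible
reduction in regression MSE. Results are insensitive to `K` over a
wide range; 50 genes per block leaves ample blocks (≥ L+2 required)
while suppressing per-gene noise. Both are exposed as knobs.

**Conditioning.** Raw power bases on log2 ranges 0–15 are poorly
conditioned. Regressions are solved on centered/scaled predictors via
an orthogonalizing least-squares solver and the coefficients mapped
back to the ordinary power basis (exact polynomial recomposition for
LLT, linear column unscaling for NLT); results match normal equations
on well-conditioned toy inputs to 1e-8. Rank-deficient designs raise
an error naming the sample.

**Identifiability.** Both transforms estimate bias relative to the
cohort mean profile `ḡ`. A distortion shared by every sample is
invisible to them; corrections are therefore defined up to the cohort
consensus scale. This shapes the synthetic generator (below) and the
interpretation of "recovering truth".

## Synthetic data

The generator emulates the empirical shape of preprocessed cohort
matrices: true log2 gene means uniform on [3, 12] (the post-filter
range, spanning ~9 log2 units); constant per-gene across-sample sd 0.5
(matching the observed flatness of the sd-vs-mean profile on the log
scale; a mean-linked sd option exists for detection-rate studies);
optional equicorrelated gene blocks; per-sample cubic distortions
`measured = p_m(truth) + ε` with `|p_m(g) − g| ≤ 0.3` over the mean
range, drawn in a Chebyshev basis with uniform coefficients; and
additive residual noise of sd 0.1. Default cohort size is 8,000 genes
by 400 samples. All draws are pure functions of the seed.

The distortion coefficients are **centered across the cohort**
(`Σ_m d_m ≡ 0`, rescaled if centering pushes a sample past the
amplitude bound): since any consensus-referenced correction can only
recover truth up to the cohort-average distortion, centering fixes
that gauge and makes "truth" a well-defined recovery target.

What the generator does **not** emulate: count-level (negative
binomial) noise and zero inflation, gene-length and GC effects,
library-preparation batch structure, realistic correlation networks
(only block equicorrelation), and heavy-tailed per-gene distributions.
Passing recovery tests therefore demonstrates that the estimation
machinery inverts polynomial per-sample warps at realistic noise
levels — not that real cohort distortions are exactly cubic.

## Evaluation

* **t statistics**: pooled equal-variance two-sample form with
  `dof = nA + nB − 2`; the single-patient statistic is the same form
  with a singleton group (the patient contributes no variance). Zero
  pooled variance raises an error naming the gene.
* **Spiking**: adding `log2(1 + C/100)` to chosen genes in a chosen
  subpopulation, exact on the raw scale when `c = 0` and within the
  offset bound otherwise. By default every gene is spiked and
  statistics are still computed gene by gene, modeling the
  single-spiked-gene situation; corrections are fitted and applied to
  the *unspiked* matrix first, then the spike is injected into the
  corrected values.
* **Resampling ensembles**: per-draw ccdf (fraction of statistics
  strictly exceeding each grid point) and per-draw empirical ROC read
  as TPR as a function of FPR, averaged pointwise across draws, with
  10th/90th percentile bands. Spiked and null draws are paired on the
  same subpopulation split (identical per-draw generator streams).
  Ties in the ranking statistic are averaged over the tied block
  (diagonal ROC segment). Bands are widened where necessary to
  bracket the mean: for strongly skewed draws (near-degenerate tails)
  a raw percentile can fall on the far side of the mean. The
  full-scale draw count in cohort studies is 5,000; tests here use
  50–200 draws.
* **Multigene tests**: the per-gene t values, each with probability
  weight 1/N, are binned on a uniform lattice (default width 0.01
  t-units) and self-convolved k-fold; the convolution is renormalized
  to guard drift and the grids extend so support is never truncated.
  The multigene ROC sweeps a threshold over the two convolved (spiked
  and null) distributions with pure step evaluation — at a target FPR
  it reports the TPR of the best threshold whose FPR does not exceed
  it.
* **Detection rate by expression level**: over repeated subpopulation
  draws, the fraction of spiked genes whose t exceeds a threshold,
  averaged in blocks of (default) 800 consecutive genes sorted by
  mean expression.
* **Correlations**: Spearman with average ranks for ties, computed
  across samples for all or sampled gene pairs; pairs with a constant
  member are skipped and counted. Difference distributions compare
  the same pair list under two transforms, optionally restricted to
  pairs whose gene means (of the first matrix) fall in a window.

## Numerical and degenerate-input conventions

Trailing partial blocks are always dropped (detection, fitting,
windowed profiles, detection-rate blocks). Mean-sort ties break by
gene id. The variance floor in LLT weights is 1e-8. `c = 0` with any
zero raw entry is an error (would produce −∞). A spike level of 0, an
identity distortion, and a zero-coefficient LLT model are exact
identities. Zero-sd genes yield constant rows in the matched-Gaussian
reference. Degenerate detection thresholds (nothing detectable) yield
all-zero rates rather than an error.

## Problem sizes used in the test suite

Unit and property tests run on matrices of 50–4,000 genes and 5–200
samples; recovery and calibration checks use 2,000–8,000 genes with
20–100 samples, 50–200 resampling draws, and 20–50 replicate seeds.
These sizes were chosen so that Monte-Carlo noise sits well below each
asserted effect while the full suite stays fast.

## Known limitations

* Corrections are defined only up to the cohort consensus scale; a
  warp common to all samples is uncorrectable by construction.
* Polynomial calibration extrapolates in each sample's expression
  tails beyond the outermost blocks, where its error is largest; no
  invertibility of `α_m` is enforced.
* Each sample is fitted independently; no hierarchical pooling across
  samples.
* The mean-expression filter is applied once and not revisited after
  correction.
* Real-cohort curve values (which depend on the particular datasets'
  correlation structure) are outside the scope of the synthetic
  benchmarks here.
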