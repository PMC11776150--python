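# scale-leveler

Detection and correction of **per-sample, expression-level-dependent
scale distortion** in bulk RNA-seq expression matrices, together with a
spiking/resampling framework for measuring what the corrections buy in
downstream statistics.

## The problem

Conventional between-sample normalizations (TPM, FPKM, TMM, RLE, ...)
rescale every gene in a sample by one multiplicative factor. On the
log2 scale that is a single additive shift per sample. But cohort
RNA-seq matrices also carry a subtler artifact: each sample's measured
log expression is warped by a smooth, sample-specific function of the
expression level itself. Block-averaging genes sorted by mean
expression amplifies this systematic warp far above the per-gene noise
(a block of B genes shrinks independent noise by 1/√B), making it
directly visible as per-sample trends in centered block-deviation
profiles — trends that no overall multiplicative factor can remove.
Left uncorrected, the warp inflates between-sample variance, biases
gene–gene correlation distributions, and costs sensitivity in
two-population *t* tests.

`scale-leveler` is for analysts of cohort expression matrices (one
sample per patient, genes × samples, raw counts / TPM / FPKM) who want
to diagnose this bias, remove it, and quantify the effect of removal.

## The model

All analysis is on the offset log scale `g = log2(x + c)` with
`c = 0.25` by default (the expected value of a level uniform on
[0, 0.5) that integer quantification rounded down to zero). Writing
`g_nm` for the measured log expression of gene *n* in sample *m*,
`ḡ_n` for its across-sample mean, and `G_nm` for the true value, three
nested corrections are provided:

* **shift** — `Ĝ_nm = g_nm − s_m`, with `s_m` the sample's mean
  deviation from the cohort profile (a multiplicative renormalization
  on the raw scale);
* **LLT** (local leveling transform) — the bias is a per-sample
  polynomial in the gene's *cohort mean* level,
  `g_nm = G_nm + β_m(ḡ_n) + ε_nm`, `β_m(u) = Σ_ℓ b_mℓ u^ℓ`; the
  coefficients are estimated by weighted least squares of
  block-averaged deviations `⟨g_nm − ḡ_n⟩_K` on powers of `⟨ḡ_n⟩_K`
  (weights = inverse block-averaged across-sample variance) and the
  fitted polynomial subtracted;
* **NLT** (nonlinear transform) — the measurement is a per-sample
  change of scale of the sample's *own* level,
  `G_nm = α_m(g_nm) + ε_nm`, `α_m(g) = Σ_ℓ a_mℓ g^ℓ`; the
  coefficients come from ordinary least squares of `⟨ḡ_n⟩_K` on the
  block averages of per-sample powers `⟨g_nm^ℓ⟩_K`, and the corrected
  value is `α̂_m` evaluated entrywise.

Defaults are cubic polynomials (`L = 3`) fitted on blocks of `K = 50`
consecutive genes in mean-sorted order.

To measure the payoff, the evaluation module **spikes** controlled
differential expression into the data — adding `log2(1 + C/100)` to
selected genes in a random subpopulation, i.e. a C% raw-scale
enhancement — and summarizes pooled-variance *t* statistics over many
resampled subpopulations as mean ccdf and averaged ROC curves with
10th/90th percentile bands, plus multigene (convolution) and
single-patient variants, and Spearman correlation distributions.

## Worked example

```python
import numpy as np
from scale_leveler import (SyntheticConfig, generate_synthetic_dataset,
                           fit_nlt, apply_nlt, variance_profile)

cfg = SyntheticConfig(n_genes=4000, n_samples=60, noise_sd=0.1, seed=42)
truth, measured, echo = generate_synthetic_dataset(cfg)   # known distortions

model = fit_nlt(measured)             # cubic alpha_m per sample, K=50
corrected = apply_nlt(measured, model)

err_before = np.median(np.abs(measured.values - truth.values))
err_after = np.median(np.abs(corrected.values - truth.values))
print(f"median |error| vs truth: {err_before:.3f} -> {err_after:.3f} log2 units")

vp_before = variance_profile(measured, window=200, statistic="variance")
vp_after = variance_profile(corrected, window=200, statistic="variance")
frac = np.mean(vp_after.avg_sd_or_var <= vp_before.avg_sd_or_var)
print(f"windows with reduced inter-sample variance: {frac:.0%}")
```

prints

```
median |error| vs truth: 0.081 -> 0.068 log2 units
windows with reduced inter-sample variance: 100%
```

The synthetic cohort carries gentle per-sample cubic distortions (up to
0.3 log2 units) plus residual noise of sd 0.1; the fitted nonlinear
transform pulls the median per-entry error down toward that noise
floor and lowers the block-averaged inter-sample variance across the
whole expression range.

The same operations are available from the shell:

```sh
scale-leveler simulate --config sim.yaml --out-truth truth.tsv --out-measured measured.tsv
scale-leveler correct --input measured.tsv --method nlt --output corrected.tsv --model-out model.tsv
scale-leveler diagnose --input measured.tsv --block-size 1000 --seed 7 --out profile.tsv
scale-leveler evaluate --measured measured.tsv --methods tpm,llt,nlt \
    --spike-levels 0,20,40 --subpop-sizes 10,50 --draws 200 --seed 7 --out results/
```

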