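"""Statistical evaluation: t tests, resampled ccdf/ROC ensembles,
multigene convolution tests and correlation distributions.

The spiking framework measures how a correction changes test behavior:
draw a random subpopulation, spike selected genes in it by
log2(1 + C/100), compute per-gene pooled-variance t statistics between
the subpopulation and the rest, and repeat over many draws.  Summaries
are the complementary CDF of the t values (fraction exceeding each
threshold) and the averaged ROC curve, where each draw's empirical ROC
is read as TPR as a function of FPR and the curves are averaged
pointwise, with 10th/90th percentile bands.

Multigene tests treat the genes as a probability space with weight 1/N
each; the distribution of a sum of k random gene t values is the k-fold
self-convolution of the binned t histogram, and threshold sweeps over
the two convolved (spiked and null) distributions yield the multigene
ROC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

CCDF = "ccdf"
ROC = "roc"


# ---------------------------------------------------------------------------
# t statistics


@dataclass
class TStatVector:
    """Per-gene pooled-variance two-sample t statistics."""

    t: np.ndarray
    dof: int
    group_sizes: tuple[int, int]


def _group_stats(vals: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = vals[:, idx]
    mean = sub.mean(axis=1)
    if len(idx) > 1:
        var = sub.var(axis=1, ddof=1)
    else:
        var = np.zeros(vals.shape[0])
    return mean, var


def two_population_t(
    m: ExpressionMatrix, groupA: Sequence[int], groupB: Sequence[int]
) -> TStatVector:
    """Pooled equal-variance t per gene, oriented B minus A.

    t = (mean_B - mean_A) / (s_p * sqrt(1/nA + 1/nB)) with
    s_p^2 = ((nA-1) s_A^2 + (nB-1) s_B^2) / (nA + nB - 2).
    Per-gene standardization happens here and only here.
    """
    a = np.unique(np.asarray(groupA, dtype=int))
    b = np.unique(np.asarray(groupB, dtype=int))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    nA, nB = len(a), len(b)
    dof = nA + nB - 2
    if dof < 1:
        raise ValueError("need nA + nB >= 3 for a pooled t statistic")
    meanA, varA = _group_stats(m.values, a)
    meanB, varB = _group_stats(m.values, b)
    sp2 = ((nA - 1) * varA + (nB - 1) * varB) / dof
    bad = sp2 <= 0
    if bad.any():
        gene = m.gene_ids[np.argmax(bad)]
        raise ValueError(f"zero pooled variance for gene {gene!r}")
    t = (meanB - meanA) / np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    return TStatVector(t=t, dof=dof, group_sizes=(nA, nB))


def single_patient_t(
    m: ExpressionMatrix, patient: int, reference_group: Sequence[int]
) -> np.ndarray:
    """Per-gene statistic for one patient against a reference population.

    z = (g_patient - mean_ref) / (s_ref * sqrt(1 + 1/n_ref)); this is
    the pooled two-sample t with a singleton group, which contributes no
    variance of its own.
    """
    ref = np.unique(np.asarray(reference_group, dtype=int))
    if patient in ref:
        raise ValueError("reference group must exclude the patient")
    if len(ref) < 2:
        raise ValueError("reference group must have at least 2 samples")
    mean_ref, var_ref = _group_stats(m.values, ref)
    if np.any(var_ref <= 0):
        gene = m.gene_ids[np.argmax(var_ref <= 0)]
        raise ValueError(f"zero reference variance for gene {gene!r}")
    n = len(ref)
    return (m.values[:, patient] - mean_ref) / np.sqrt(var_ref * (1.0 + 1.0 / n))


# ---------------------------------------------------------------------------
# resampling ensembles


@dataclass
class ResamplingEnsemble:
    """Per-draw curves with mean and 10th/90th percentile bands.

    Bands are percentiles of the per-draw curves, widened where
    necessary so that band_lo <= mean <= band_hi holds pointwise (with
    strongly skewed draws a raw percentile can fall on the far side of
    the mean).
    """

    curve_kind: str
    grid: np.ndarray
    per_draw: np.ndarray      # (R, len(grid))
    mean_curve: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    R: int
    seed: int | None


def _make_ensemble(kind: str, grid: np.ndarray, per_draw: np.ndarray,
                   seed) -> ResamplingEnsemble:
    mean = per_draw.mean(axis=0)
    lo = np.minimum(np.percentile(per_draw, 10, axis=0), mean)
    hi = np.maximum(np.percentile(per_draw, 90, axis=0), mean)
    return ResamplingEnsemble(
        curve_kind=kind, grid=grid, per_draw=per_draw, mean_curve=mean,
        band_lo=lo, band_hi=hi, R=per_draw.shape[0], seed=seed,
    )


def ccdf_curve(t_values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fraction of statistics strictly exceeding each grid point."""
    s = np.sort(np.asarray(t_values, dtype=float))
    return (s.size - np.searchsorted(s, grid, side="right")) / s.size


def ccdf_ensemble(
    runner: Callable[[np.random.Generator], np.ndarray],
    grid: np.ndarray,
    R: int,
    seed: int | None = None,
) -> ResamplingEnsemble:
    """Mean ccdf with 10/90 bands over R draws from ``runner``.

    ``runner`` receives a fresh per-draw Generator and returns that
    draw's per-gene statistics.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if R < 1:
        raise ValueError("R must be >= 1")
    children = np.random.SeedSequence(seed).spawn(R)
    per_draw = np.empty((R, grid.size))
    for r in range(R):
        t = runner(np.random.default_rng(children[r]))
        per_draw[r] = ccdf_curve(t, grid)
    return _make_ensemble(CCDF, grid, per_draw, seed)


def _tpr_at(pts_f: np.ndarray, pts_t: np.ndarray, grid: np.ndarray,
            step: bool = False) -> np.ndarray:
    """Evaluate a threshold-sweep curve at known FPR values.

    Consecutive points delimit the effect of a single threshold block.
    By default, segments that move in both coordinates (ties spanning
    positives and negatives) are interpolated linearly — averaging over
    the tied block — and all others behave as steps; ``step=True``
    forces pure step evaluation (the TPR of the best threshold with
    FPR <= f).
    """
    idx = np.searchsorted(pts_f, grid, side="right") - 1
    idx = np.clip(idx, 0, len(pts_f) - 1)
    out = pts_t[idx].astype(float)
    if not step:
        nxt = np.minimum(idx + 1, len(pts_f) - 1)
        df = pts_f[nxt] - pts_f[idx]
        interp = (df > 0) & (grid > pts_f[idx])
        out[interp] += (
            (pts_t[nxt] - pts_t[idx])[interp]
            * (grid[interp] - pts_f[idx][interp])
            / df[interp]
        )
    return np.clip(out, 0.0, 1.0)


def empirical_roc(
    pos_scores: np.ndarray, neg_scores: np.ndarray, fpr_grid: np.ndarray
) -> np.ndarray:
    """TPR as a function of FPR for one draw, by threshold sweep.

    Genes are ranked by score; sweeping the threshold downward yields
    step points (FPR, TPR).  Ties in score are resolved by averaging
    over the tied block (a diagonal segment).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    sp, sn = np.sort(pos), np.sort(neg)
    tpr = (pos.size - np.searchsorted(sp, thr, side="left")) / pos.size
    fpr = (neg.size - np.searchsorted(sn, thr, side="left")) / neg.size
    pts_f = np.concatenate([[0.0], fpr])
    pts_t = np.concatenate([[0.0], tpr])
    return _tpr_at(pts_f, pts_t, np.asarray(fpr_grid, dtype=float))


def roc_ensemble(
    spiked_runner: Callable[[np.random.Generator], np.ndarray],
    null_runner: Callable[[np.random.Generator], np.ndarray],
    fpr_grid: np.ndarray,
    R: int,
    seed: int | None = None,
    positive_mask: np.ndarray | None = None,
) -> ResamplingEnsemble:
    """Averaged ROC over R paired spiked/null draws.

    Both runners receive Generators seeded identically per draw, so a
    runner that draws the subpopulation split internally produces the
    *same* split for the spiked and the matched null computation.
    Positives are the spiked genes' statistics from the spiked run;
    negatives are the unspiked genes' statistics from the null run (all
    genes when every gene is spiked, ``positive_mask`` selecting a
    subset otherwise).
    """
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    if fpr_grid.size == 0:
        raise ValueError("fpr_grid must be non-empty")
    if R < 1:
        raise ValueError("R must be >= 1")
    children = np.random.SeedSequence(seed).spawn(R)
    per_draw = np.empty((R, fpr_grid.size))
    for r in range(R):
        # identical per-draw streams => identical subpopulation splits
        t_spiked = spiked_runner(np.random.default_rng(children[r]))
        t_null = null_runner(np.random.default_rng(children[r]))
        if positive_mask is None:
            pos, neg = t_spiked, t_null
        else:
            mask = np.asarray(positive_mask, dtype=bool)
            pos = t_spiked[mask]
            neg = t_null[~mask] if (~mask).any() else t_null[mask]
        per_draw[r] = empirical_roc(pos, neg, fpr_grid)
    return _make_ensemble(ROC, fpr_grid, per_draw, seed)


# ---------------------------------------------------------------------------
# multigene convolution tests


@dataclass
class SumStatDistribution:
    """Binned distribution of sums of k random gene t statistics."""

    n_genes_summed: int
    bin_grid: np.ndarray
    probabilities: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def multigene_sum_distribution(
    t: TStatVector | np.ndarray, k: int, bin_width: float = 0.01
) -> SumStatDistribution:
    """k-fold self-convolution of the binned per-gene t distribution.

    Each gene carries probability weight 1/N; the t values are binned
    on a uniform lattice of ``bin_width``, convolved k-1 times, and
    renormalized to guard against drift.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = t.t if isinstance(t, TStatVector) else np.asarray(t, dtype=float)
    idx = np.rint(vals / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    base = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
    base /= base.sum()
    probs = base
    for _ in range(k - 1):
        probs = np.convolve(probs, base)
    probs /= probs.sum()
    start = k * lo
    grid = (start + np.arange(probs.size)) * bin_width
    return SumStatDistribution(
        n_genes_summed=k, bin_grid=grid, probabilities=probs,
        bin_width=float(bin_width),
    )


def multigene_roc(
    spiked_dist: SumStatDistribution,
    null_dist: SumStatDistribution,
    fpr_grid: np.ndarray,
) -> np.ndarray:
    """ROC by threshold sweep over two sum-statistic distributions.

    At threshold tau: FPR = P_null(S > tau), TPR = P_spiked(S > tau);
    the curve is reported as TPR at each requested FPR grid point.
    """
    if abs(spiked_dist.bin_width - null_dist.bin_width) > 1e-12:
        raise ValueError("distributions must share the same bin width")
    if spiked_dist.n_genes_summed != null_dist.n_genes_summed:
        raise ValueError("distributions must sum the same number of genes")
    thr = np.unique(np.concatenate([spiked_dist.bin_grid, null_dist.bin_grid]))[::-1]

    def _ccdf(dist: SumStatDistribution) -> np.ndarray:
        # P(S > tau) for each tau: exclude mass at the threshold itself
        order = np.searchsorted(dist.bin_grid, thr, side="right")
        tail = np.concatenate([np.cumsum(dist.probabilities[::-1])[::-1], [0.0]])
        return tail[order]

    fpr = _ccdf(null_dist)
    tpr = _ccdf(spiked_dist)
    pts_f = np.concatenate([[0.0], fpr, [1.0]])
    pts_t = np.concatenate([[0.0], tpr, [1.0]])
    keep = np.argsort(pts_f, kind="stable")
    return _tpr_at(pts_f[keep], pts_t[keep], np.asarray(fpr_grid, dtype=float),
                   step=True)


# ---------------------------------------------------------------------------
# detection rate and correlations


def detection_rate_by_expression(
    m: ExpressionMatrix,
    design,
    t_threshold: float,
    block: int = 800,
    R: int = 100,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detection rate of spiked genes, block-averaged along expression level.

    Over R random subpopulation draws (size taken from the design), the
    design's genes are spiked, per-gene t statistics computed between
    the subpopulation and the rest, and a spiked gene counts as
    detected when t exceeds the threshold.  Rates are averaged over
    draws, then over blocks of ``block`` consecutive spiked genes in
    mean-expression-sorted order.  Returns (block mean expression,
    block detection rate).
    """
    from .simulation import SpikeDesign, spike  # local import to avoid cycle

    if block < 1 or block > m.n_genes:
        raise ValueError("block must satisfy 1 <= block <= n_genes")
    genes = np.asarray(design.spiked_genes, dtype=int)
    if genes.size // block < 1:
        raise ValueError("fewer spiked genes than one block")
    P = int(np.asarray(design.subpopulation).size)
    rng = np.random.default_rng(seed)
    hits = np.zeros(genes.size)
    all_idx = np.arange(m.n_samples)
    for _ in range(R):
        sub = rng.choice(m.n_samples, size=P, replace=False)
        d = SpikeDesign(subpopulation=sub, spiked_genes=genes,
                        spike_level_percent=design.spike_level_percent)
        spiked = spike(m, d)
        rest = np.setdiff1d(all_idx, sub)
        t = two_population_t(spiked, rest, sub).t
        hits += t[genes] > t_threshold
    rates = hits / R
    means = m.values.mean(axis=1)[genes]
    order = np.argsort(means, kind="stable")
    from .bias_detection import _block_reduce

    grid = _block_reduce(means[order][:, None], block)[:, 0]
    rate_blocks = _block_reduce(rates[order][:, None], block)[:, 0]
    return grid, rate_blocks


@dataclass
class CorrelationDistribution:
    correlations: np.ndarray
    mean: float
    sd: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_skipped: int


def _rank_rows(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values, axis=1)
    return ranks - ranks.mean(axis=1, keepdims=True)


def _pair_spearman(cr: np.ndarray, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho per (i, j) pair from centered rank rows.

    Returns (rho, valid-mask); pairs with a constant member are invalid.
    """
    a = cr[pairs[:, 0]]
    b = cr[pairs[:, 1]]
    na = np.sqrt((a ** 2).sum(axis=1))
    nb = np.sqrt((b ** 2).sum(axis=1))
    valid = (na > 0) & (nb > 0)
    rho = np.full(pairs.shape[0], np.nan)
    rho[valid] = (a[valid] * b[valid]).sum(axis=1) / (na[valid] * nb[valid])
    return rho, valid


def _sample_pairs(N: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    i = rng.integers(0, N, size=n_pairs)
    j = rng.integers(0, N, size=n_pairs)
    clash = i == j
    while clash.any():
        j[clash] = rng.integers(0, N, size=clash.sum())
        clash = i == j
    return np.column_stack([i, j])


def correlation_distribution(
    m: ExpressionMatrix,
    n_pairs: int | None = None,
    seed: int | None = None,
    n_bins: int = 80,
) -> CorrelationDistribution:
    """Distribution of gene-gene Spearman correlations across samples.

    Uses average ranks for ties.  ``n_pairs=None`` correlates all gene
    pairs; otherwise that many random pairs are sampled.  Pairs with a
    constant member are skipped and counted.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    cr = _rank_rows(m.values)
    if n_pairs is None:
        iu = np.triu_indices(m.n_genes, k=1)
        pairs = np.column_stack(iu)
    else:
        pairs = _sample_pairs(m.n_genes, int(n_pairs), np.random.default_rng(seed))
    rho, valid = _pair_spearman(cr, pairs)
    rho = rho[valid]
    counts, edges = np.histogram(rho, bins=n_bins, range=(-1.0, 1.0))
    return CorrelationDistribution(
        correlations=rho,
        mean=float(rho.mean()) if rho.size else float("nan"),
        sd=float(rho.std(ddof=1)) if rho.size > 1 else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
        n_skipped=int((~valid).sum()),
    )


def correlation_difference_distribution(
    mA: ExpressionMatrix,
    mB: ExpressionMatrix,
    pairs: np.ndarray,
    mean_range: tuple[float, float] | None = None,
) -> CorrelationDistribution:
    """Per-pair Spearman differences rho_A - rho_B over a shared pair list.

    ``mean_range=(lo, hi)`` restricts to pairs whose two genes both
    have mean expression (computed on ``mA``) inside [lo, hi].
    """
    if not mA.same_genes(mB):
        raise ValueError("matrices must share the same gene set and order")
    pairs = np.asarray(pairs, dtype=int)
    if mean_range is not None:
        lo, hi = mean_range
        means = mA.values.mean(axis=1)
        ok = ((means[pairs[:, 0]] >= lo) & (means[pairs[:, 0]] <= hi)
              & (means[pairs[:, 1]] >= lo) & (means[pairs[:, 1]] <= hi))
        pairs = pairs[ok]
    rhoA, va = _pair_spearman(_rank_rows(mA.values), pairs)
    rhoB, vb = _pair_spearman(_rank_rows(mB.values), pairs)
    valid = va & vb
    diff = (rhoA - rhoB)[valid]
    counts, edges = np.histogram(diff, bins=80, range=(-2.0, 2.0))
    return CorrelationDistribution(
        correlations=diff,
        mean=float(diff.mean()) if diff.size else float("nan"),
        sd=float(diff.std(ddof=1)) if diff.size > 1 else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
        n_skipped=int((~valid).sum()),
    )
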