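"""Diagnostics that expose per-sample, expression-level-dependent bias.

Per-gene deviations from the cohort mean are noisy; block averaging over
genes sorted by mean expression amplifies small systematic shifts
relative to the per-gene noise (a block of B genes shrinks independent
noise by 1/sqrt(B) while a smooth bias survives intact).  Comparing the
centered block-deviation profile computed over the sorted order with the
same profile over a random gene order separates expression-level-
dependent bias (trends in the sorted profile) from overall per-sample
normalization shifts (flat offsets in the unsorted profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import LOG2_OFFSET, ExpressionMatrix

SORTED_BY_MEAN = "sorted_by_mean"
GIVEN_RANDOM_ORDER = "given_random_order"


def _require_log(m: ExpressionMatrix) -> None:
    if m.scale != LOG2_OFFSET:
        raise ValueError("operation requires a log2-offset scale matrix")


def gene_means(m: ExpressionMatrix) -> np.ndarray:
    """Across-sample mean expression per gene (log2 units)."""
    _require_log(m)
    return m.values.mean(axis=1)


def gene_deviations(m: ExpressionMatrix) -> np.ndarray:
    """Per-entry deviation from the gene's across-sample mean; rows sum to 0."""
    _require_log(m)
    return m.values - m.values.mean(axis=1, keepdims=True)


def sort_order(m: ExpressionMatrix) -> np.ndarray:
    """Gene permutation sorting means ascending; ties broken by gene id."""
    means = gene_means(m)
    # lexsort: last key is primary
    return np.lexsort((m.gene_ids.astype(str), means))


@dataclass
class GeneSummary:
    mean: np.ndarray
    variance: np.ndarray
    order: np.ndarray


def summarize_genes(m: ExpressionMatrix) -> GeneSummary:
    """Per-gene mean, unbiased across-sample variance, and mean-sort order."""
    _require_log(m)
    var = m.values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_genes)
    return GeneSummary(mean=gene_means(m), variance=var, order=sort_order(m))


@dataclass
class BlockProfile:
    """Per-sample block averages over a gene ordering, raw and centered."""

    block_size: int
    n_blocks: int
    ordering: str
    block_means_expression: np.ndarray  # (n_blocks,)
    raw: np.ndarray       # (n_blocks, n_samples) block averages b_km
    centered: np.ndarray  # (n_blocks, n_samples) deviations from block means


def _block_reduce(x: np.ndarray, B: int) -> np.ndarray:
    """Average consecutive groups of B rows; trailing remainder dropped."""
    K = x.shape[0] // B
    return x[: K * B].reshape(K, B, *x.shape[1:]).mean(axis=1)


def block_profile(
    m: ExpressionMatrix,
    B: int,
    ordering: str = SORTED_BY_MEAN,
    seed: int | None = None,
) -> BlockProfile:
    """Block averages of expression over sorted or random gene order.

    Genes are arranged in the requested order, divided into
    floor(N/B) consecutive blocks of B (remainder dropped), and each
    block averaged per sample.  Centered values subtract the
    across-sample mean of each block, so a flat nonzero centered curve
    is an overall per-sample shift and a trending curve is an
    expression-level-dependent bias.
    """
    _require_log(m)
    if B < 1:
        raise ValueError("block size must be >= 1")
    if B > m.n_genes:
        raise ValueError(f"block size {B} exceeds gene count {m.n_genes}")
    if ordering == SORTED_BY_MEAN:
        order = sort_order(m)
    elif ordering in (GIVEN_RANDOM_ORDER, "random"):
        rng = np.random.default_rng(seed)
        order = rng.permutation(m.n_genes)
        ordering = GIVEN_RANDOM_ORDER
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    g = m.values[order]
    means = g.mean(axis=1)
    raw = _block_reduce(g, B)
    centered = raw - raw.mean(axis=1, keepdims=True)
    return BlockProfile(
        block_size=int(B),
        n_blocks=raw.shape[0],
        ordering=ordering,
        block_means_expression=_block_reduce(means[:, None], B)[:, 0],
        raw=raw,
        centered=centered,
    )


@dataclass
class VarianceProfile:
    window: int
    mean_grid: np.ndarray
    avg_sd_or_var: np.ndarray
    statistic: str  # "sd" or "variance"


def variance_profile(
    m: ExpressionMatrix,
    window: int = 800,
    statistic: str = "sd",
    moving: bool = False,
) -> VarianceProfile:
    """Windowed average of per-gene sd (or variance) along the mean-sorted order.

    With ``moving=False`` the windows are non-overlapping and tile the
    sorted order (remainder dropped); with ``moving=True`` a centered
    moving average of the same width is returned at every gene.
    """
    _require_log(m)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > m.n_genes:
        raise ValueError(f"window {window} exceeds gene count {m.n_genes}")
    if statistic not in ("sd", "variance"):
        raise ValueError("statistic must be 'sd' or 'variance'")
    order = sort_order(m)
    means = m.values.mean(axis=1)[order]
    var = m.values.var(axis=1, ddof=1)[order]
    stat = np.sqrt(var) if statistic == "sd" else var
    if moving:
        kernel = np.ones(window) / window
        grid = np.convolve(means, kernel, mode="valid")
        prof = np.convolve(stat, kernel, mode="valid")
    else:
        grid = _block_reduce(means[:, None], window)[:, 0]
        prof = _block_reduce(stat[:, None], window)[:, 0]
    return VarianceProfile(window=int(window), mean_grid=grid,
                           avg_sd_or_var=prof, statistic=statistic)


def normality_sweep(
    m: ExpressionMatrix, group_size: int = 1, seed: int | None = None
) -> np.ndarray:
    """Sorted per-gene d'Agostino omnibus p-values, optionally on group means.

    With ``group_size > 1`` the samples are randomly partitioned into
    floor(M/group_size) disjoint groups and per-gene group means replace
    the per-sample values, mimicking the averaging that two-population
    test statistics perform; by the central limit theorem the averages
    are closer to normal than the raw values.  The sorted p-value curve
    is intended for plotting against uniform quantiles: a diagonal curve
    is consistent with normality.
    """
    _require_log(m)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n_groups = m.n_samples // group_size
    data = m.values
    if group_size > 1:
        if n_groups < 2:
            raise ValueError("group_size leaves fewer than 2 groups")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(m.n_samples)[: n_groups * group_size]
        grouped = data[:, perm].reshape(m.n_genes, n_groups, group_size)
        data = grouped.mean(axis=2)
    if data.shape[1] < 8:
        raise ValueError(
            "d'Agostino omnibus test needs at least 8 observations per gene"
        )
    _, pvals = stats.normaltest(data, axis=1)
    return np.sort(pvals)
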