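"""Synthetic expression data with known truth, distortion and spiking.

The generator emulates the empirical shape of preprocessed bulk RNA-seq
matrices on the log2 scale: per-gene true means spanning several log2
units, per-gene across-sample variability roughly independent of the
mean, optional equicorrelated gene blocks, and — the object of study —
per-sample polynomial scale distortions applied in the forward
direction, measured = p_m(truth) + noise.  Because the distortion
polynomials are known, corrections can be judged against ground truth.

Spiking creates controlled differential expression purely in the data:
adding log2(1 + C/100) to selected genes in a selected subpopulation is
equivalent to multiplying the raw-scale values by (1 + C/100) (exactly
when the log offset c = 0, and to within the offset distortion bound
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import Chebyshev, Polynomial

from .matrix import LOG2_OFFSET, ExpressionMatrix


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a cohort-scale matrix: 8,000 genes, 400 samples,
    true log2 means uniform on [3, 12], constant across-sample sd 0.5
    (variance flat in the mean), gentle per-sample cubic distortions
    bounded by ``distortion_amplitude`` log2 units, and additive
    residual noise with sd 0.1.
    """

    n_genes: int = 8000
    n_samples: int = 400
    mean_low: float = 3.0
    mean_high: float = 12.0
    gene_sd: float | tuple[float, float] = 0.5
    correlation_block_size: int | None = None
    correlation_rho: float = 0.0
    distortion: str | np.ndarray | None = "gentle_cubic"
    distortion_amplitude: float = 0.3
    noise_sd: float = 0.1
    offset_c: float = 0.25
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.mean_high < self.mean_low:
            raise ValueError("mean_high must be >= mean_low")
        sds = self.gene_sd if isinstance(self.gene_sd, tuple) else (self.gene_sd,)
        if any(s < 0 for s in sds):
            raise ValueError("gene_sd must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not -1 < self.correlation_rho < 1:
            raise ValueError("correlation_rho must lie in (-1, 1)")
        if self.correlation_rho != 0 and not self.correlation_block_size:
            raise ValueError("correlated blocks need correlation_block_size")
        if self.distortion_amplitude < 0:
            raise ValueError("distortion_amplitude must be nonnegative")


def _gentle_cubic_coefs(
    rng: np.random.Generator, n_samples: int, low: float, high: float, amp: float
) -> np.ndarray:
    """Per-sample cubic distortion polynomials p_m with |p_m(g) - g| <= amp.

    The deviation d_m is drawn in the Chebyshev basis on [low, high]
    with coefficients uniform on +-amp/4, so sum |e_i| <= amp bounds the
    deviation on the range.  The coefficients are then centered across
    the cohort (sum_m d_m = 0 exactly, rescaled if centering pushes a
    sample past the bound): a per-sample scale distortion is only
    identifiable relative to the cohort consensus scale, so synthetic
    truth is defined on that consensus.  Returned as (n_samples, 4)
    power-basis coefficients of p_m(g) = g + d_m(g).
    """
    e = rng.uniform(-amp / 4.0, amp / 4.0, size=(n_samples, 4))
    if n_samples > 1:
        e -= e.mean(axis=0, keepdims=True)
        worst = np.abs(e).sum(axis=1).max()
        if worst > amp > 0:
            e *= amp / worst
    coefs = np.empty((n_samples, 4))
    for j in range(n_samples):
        d = Chebyshev(e[j], domain=[low, high]).convert(kind=Polynomial)
        c = np.zeros(4)
        c[: len(d.coef)] = d.coef
        c[1] += 1.0
        coefs[j] = c
    return coefs


def resolve_distortions(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Materialize the per-sample distortion polynomials as an (M, L+1) array."""
    if cfg.distortion is None:
        return np.tile(np.array([0.0, 1.0]), (cfg.n_samples, 1))
    if isinstance(cfg.distortion, str):
        if cfg.distortion != "gentle_cubic":
            raise ValueError(f"unknown distortion kind {cfg.distortion!r}")
        return _gentle_cubic_coefs(
            rng, cfg.n_samples, cfg.mean_low, cfg.mean_high,
            cfg.distortion_amplitude,
        )
    arr = np.atleast_2d(np.asarray(cfg.distortion, dtype=float))
    if arr.shape[0] == 1:
        arr = np.tile(arr, (cfg.n_samples, 1))
    if arr.shape[0] != cfg.n_samples:
        raise ValueError("need one distortion polynomial per sample (or one shared)")
    return arr


def generate_synthetic_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticConfig]:
    """Draw (truth, measured) matrices; fully reproducible from cfg.seed.

    Truth: G_nm = Gbar_n + correlated/independent Gaussian deviations.
    Measured: g_nm = p_m(G_nm) + eps_nm.  The returned config echo has
    ``distortion`` replaced by the materialized coefficient array.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    N, M = cfg.n_genes, cfg.n_samples
    gbar = rng.uniform(cfg.mean_low, cfg.mean_high, size=N)
    if isinstance(cfg.gene_sd, tuple):
        lo_sd, hi_sd = cfg.gene_sd
        span = max(cfg.mean_high - cfg.mean_low, 1e-12)
        sd = lo_sd + (hi_sd - lo_sd) * (gbar - cfg.mean_low) / span
    else:
        sd = np.full(N, float(cfg.gene_sd))
    z = rng.standard_normal((N, M))
    rho = cfg.correlation_rho
    if rho != 0:
        bs = int(cfg.correlation_block_size)
        n_blocks = -(-N // bs)
        shared = rng.standard_normal((n_blocks, M))
        shared_full = np.repeat(shared, bs, axis=0)[:N]
        sgn = np.sign(rho)
        z = np.sqrt(abs(rho)) * sgn * shared_full + np.sqrt(1 - abs(rho)) * z
    truth_vals = gbar[:, None] + sd[:, None] * z
    polys = resolve_distortions(cfg, rng)
    measured_vals = np.empty_like(truth_vals)
    for j in range(M):
        measured_vals[:, j] = np.polynomial.polynomial.polyval(
            truth_vals[:, j], polys[j]
        )
    if cfg.noise_sd > 0:
        measured_vals += cfg.noise_sd * rng.standard_normal((N, M))
    gene_ids = np.array([f"g{n:05d}" for n in range(N)], dtype=object)
    sample_ids = np.array([f"s{m:04d}" for m in range(M)], dtype=object)
    truth = ExpressionMatrix(truth_vals, gene_ids, sample_ids,
                             scale=LOG2_OFFSET, offset_c=cfg.offset_c)
    measured = ExpressionMatrix(measured_vals, gene_ids, sample_ids,
                                scale=LOG2_OFFSET, offset_c=cfg.offset_c)
    return truth, measured, replace(cfg, distortion=polys)


@dataclass
class SpikeDesign:
    """Which genes get raised, in whom, and by how much.

    ``spike_level_percent`` is the percent enhancement C; the additive
    log2 shift is log2(1 + C/100) by construction.
    """

    subpopulation: np.ndarray
    spiked_genes: np.ndarray
    spike_level_percent: float

    def __post_init__(self) -> None:
        self.subpopulation = np.unique(np.asarray(self.subpopulation, dtype=int))
        self.spiked_genes = np.unique(np.asarray(self.spiked_genes, dtype=int))
        if self.spike_level_percent < 0:
            raise ValueError("spike level C must be >= 0")
        if self.subpopulation.size == 0 or self.spiked_genes.size == 0:
            raise ValueError("subpopulation and spiked gene set must be non-empty")

    @property
    def log_shift(self) -> float:
        return float(np.log2(1.0 + self.spike_level_percent / 100.0))


def spike(m: ExpressionMatrix, design: SpikeDesign) -> ExpressionMatrix:
    """Add the design's log2 shift at (spiked genes x subpopulation)."""
    if m.scale != LOG2_OFFSET:
        raise ValueError("spiking operates on log2-offset scale matrices")
    if design.subpopulation.max() >= m.n_samples or design.subpopulation.min() < 0:
        raise ValueError("subpopulation indices out of range")
    if design.spiked_genes.max() >= m.n_genes or design.spiked_genes.min() < 0:
        raise ValueError("spiked gene indices out of range")
    if design.subpopulation.size >= m.n_samples:
        raise ValueError("subpopulation must be a proper subset of samples")
    out = m.values.copy()
    out[np.ix_(design.spiked_genes, design.subpopulation)] += design.log_shift
    return m.with_values(out)


def draw_subpopulations(
    M: int, P: int, R: int, seed: int | None = None
) -> list[np.ndarray]:
    """R independent uniform draws of P distinct sample indices out of M."""
    if not 1 <= P < M:
        raise ValueError("need 1 <= P < M")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(M, size=P, replace=False) for _ in range(R)]


def scramble_genes(m: ExpressionMatrix, seed: int | None = None) -> ExpressionMatrix:
    """Permute each gene's values independently across samples.

    Destroys gene-gene correlation while preserving every per-gene
    marginal distribution exactly.
    """
    rng = np.random.default_rng(seed)
    return m.with_values(rng.permuted(m.values, axis=1))


def gaussian_reference(m: ExpressionMatrix, seed: int | None = None) -> ExpressionMatrix:
    """Independent Gaussian matrix matching each gene's mean and sd.

    Genes with zero across-sample sd yield constant rows.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to match per-gene sds")
    rng = np.random.default_rng(seed)
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    vals = mu + sd * rng.standard_normal(m.values.shape)
    return m.with_values(vals)
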