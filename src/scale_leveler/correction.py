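"""Per-sample bias corrections: shift, local leveling (LLT), nonlinear (NLT).

Three corrections of increasing expressiveness, all on the log2 scale:

* **shift** — subtract each sample's mean deviation from the cohort
  gene means.  Equivalent to a per-sample multiplicative renormalization
  on the raw scale; removes the flat offsets visible in unsorted block
  profiles but cannot touch expression-level-dependent trends.

* **LLT** (local leveling transform) — model the bias for sample m as a
  polynomial beta_m(gbar_n) in the gene's *cohort mean* expression,
  estimated by weighted least squares of block-averaged deviations
  <g_nm - gbar_n>_K on powers of block-averaged means <gbar_n>_K, and
  subtract the fitted polynomial.  Blocks of K consecutive genes in the
  mean-sorted order average away per-gene noise so the smooth bias
  dominates; weights are inverse block-averaged across-sample variance,
  since inter-patient expression variation is the dominant error source.

* **NLT** (nonlinear transform) — model the measurement as a per-sample
  nonlinear change of scale of the sample's *own* level: the corrected
  value is alpha_m(g_nm) with alpha_m polynomial.  Coefficients come
  from ordinary least squares of <gbar_n>_K on the block averages of
  per-sample powers <g_nm^l>_K (note: averages of powers, not powers of
  averages — the response error here is a mixture with no clean
  variance model, hence unweighted regression).

Regressions are solved on a centered/scaled basis for conditioning and
the coefficients mapped back to the ordinary power basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .bias_detection import _block_reduce, sort_order
from .matrix import LOG2_OFFSET, ExpressionMatrix

SHIFT = "shift"
LLT = "llt"
NLT = "nlt"

VARIANCE_FLOOR = 1e-8  # floor for inverse-variance weights


@dataclass
class PatientBiasModel:
    """Per-sample polynomial bias model with fit metadata.

    ``coefficients`` has one row per sample: for ``llt`` the polynomial
    beta_m evaluated at the gene mean, for ``nlt`` the polynomial
    alpha_m evaluated at the sample's own measured value, for ``shift``
    a single constant.  ``fitted_gene_means`` snapshots the gene means
    used in fitting so fit/apply form a consistent pair.
    """

    kind: str
    order: int
    coefficients: np.ndarray      # (n_samples, order + 1)
    fit_block_size: int
    weighted: bool
    residual_mse: np.ndarray      # (n_samples,)
    fitted_gene_ids: np.ndarray
    fitted_gene_means: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("model coefficients must be finite")
        if self.order < 0:
            raise ValueError("polynomial order must be >= 0")


def _require_log(m: ExpressionMatrix) -> None:
    if m.scale != LOG2_OFFSET:
        raise ValueError("corrections are defined on log2-offset scale matrices")


def shift_correct(m: ExpressionMatrix) -> tuple[ExpressionMatrix, PatientBiasModel]:
    """Remove each sample's overall shift from the cohort mean profile.

    Subtracts s_m = (1/N) sum_n (g_nm - gbar_n) from column m; an
    additive log-space shift, i.e. a multiplicative renormalization on
    the raw scale.  Exactly idempotent.
    """
    _require_log(m)
    gbar = m.values.mean(axis=1)
    shifts = (m.values - gbar[:, None]).mean(axis=0)
    corrected = m.with_values(m.values - shifts[None, :])
    model = PatientBiasModel(
        kind=SHIFT,
        order=0,
        coefficients=shifts[:, None],
        fit_block_size=m.n_genes,
        weighted=False,
        residual_mse=np.zeros(m.n_samples),
        fitted_gene_ids=m.gene_ids,
        fitted_gene_means=gbar,
        sample_ids=m.sample_ids,
    )
    return corrected, model


def _scaled_polyfit_common(
    x: np.ndarray, Y: np.ndarray, L: int, w: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """(Weighted) polynomial LS of each column of Y on x, shared design.

    Solves on the standardized variable x_s = (x - mu)/sigma and maps
    the coefficients back to the ordinary power basis.  Returns
    (coefficients with shape (n_cols, L+1), residual mse per column).
    """
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        sigma = 1.0
    xs = (x - mu) / sigma
    A = np.vander(xs, L + 1, increasing=True)
    if w is not None:
        sw = np.sqrt(w)[:, None]
        sol, _, rank, _ = np.linalg.lstsq(A * sw, Y * sw, rcond=None)
    else:
        sol, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < L + 1:
        raise ValueError("singular regression design (rank deficient)")
    resid = Y - A @ sol
    mse = (resid ** 2).mean(axis=0)
    # map back: p(x_s) with x_s = (x - mu)/sigma
    back = Polynomial([-mu / sigma, 1.0 / sigma])
    coefs = np.empty((Y.shape[1], L + 1))
    for j in range(Y.shape[1]):
        p = Polynomial(sol[:, j])(back)
        c = p.convert().coef
        coefs[j, : len(c)] = c
        coefs[j, len(c):] = 0.0
    return coefs, mse


def _fit_blocks(m: ExpressionMatrix, L: int, K: int):
    """Shared plumbing: sorted arrays and block counts for LLT/NLT fits."""
    _require_log(m)
    if L < 0:
        raise ValueError("polynomial degree must be >= 0")
    if K < 1:
        raise ValueError("block span K must be >= 1")
    n_blocks = m.n_genes // K
    if n_blocks < L + 2:
        raise ValueError(
            f"{n_blocks} blocks of span {K} cannot identify {L + 1} coefficients"
        )
    order = sort_order(m)
    g = m.values[order]
    gbar = g.mean(axis=1)
    return g, gbar


def fit_llt(m: ExpressionMatrix, L: int = 3, K: int = 50) -> PatientBiasModel:
    """Fit the local-leveling polynomial bias model per sample.

    Weighted least squares of the block-averaged deviations
    <g_nm - gbar_n>_K on 1, <gbar_n>_K, ..., <gbar_n>_K^L with weights
    w_k = 1 / max(<Var_across-samples(g_n.)>_K, 1e-8); the design and
    weights are shared across samples, so all samples are solved in one
    pass.
    """
    g, gbar = _fit_blocks(m, L, K)
    resp = _block_reduce(g - gbar[:, None], K)              # (K_blocks, M)
    pred = _block_reduce(gbar[:, None], K)[:, 0]            # (K_blocks,)
    if m.n_samples > 1:
        var = g.var(axis=1, ddof=1)
    else:
        var = np.zeros(m.n_genes)
    block_var = _block_reduce(var[:, None], K)[:, 0]
    w = 1.0 / np.maximum(block_var, VARIANCE_FLOOR)
    try:
        coefs, mse = _scaled_polyfit_common(pred, resp, L, w)
    except ValueError as exc:
        raise ValueError(f"LLT regression failed: {exc}") from exc
    return PatientBiasModel(
        kind=LLT,
        order=L,
        coefficients=coefs,
        fit_block_size=K,
        weighted=True,
        residual_mse=mse,
        fitted_gene_ids=m.gene_ids,
        fitted_gene_means=m.values.mean(axis=1),
        sample_ids=m.sample_ids,
    )


def _aligned_means(m: ExpressionMatrix, model: PatientBiasModel) -> np.ndarray:
    """Stored fitting-time gene means, aligned to the matrix's gene order."""
    ids = m.gene_ids.astype(str)
    fit_ids = model.fitted_gene_ids.astype(str)
    if set(ids) != set(fit_ids):
        raise ValueError("model was fitted on a different gene set")
    lookup = {gid: mu for gid, mu in zip(fit_ids, model.fitted_gene_means)}
    return np.array([lookup[gid] for gid in ids])


def apply_llt(m: ExpressionMatrix, model: PatientBiasModel) -> ExpressionMatrix:
    """Subtract the fitted beta_m(gbar_n), using the stored gene-mean snapshot."""
    _require_log(m)
    if model.kind != LLT:
        raise ValueError("model kind must be 'llt'")
    gbar = _aligned_means(m, model)
    V = np.vander(gbar, model.order + 1, increasing=True)   # (N, L+1)
    bias = V @ model.coefficients.T                          # (N, M)
    return m.with_values(m.values - bias)


def fit_nlt(m: ExpressionMatrix, L: int = 3, K: int = 50) -> PatientBiasModel:
    """Fit the per-sample nonlinear rescaling alpha_m by block regression.

    For each sample m, ordinary least squares of the response
    <gbar_n>_K on predictors <g_nm^l>_K for l = 0..L.  The predictors
    are block averages of per-sample powers (not powers of block
    averages).  Columns are standardized internally and the solution
    mapped back to the ordinary power basis of alpha_m.
    """
    g, gbar = _fit_blocks(m, L, K)
    resp = _block_reduce(gbar[:, None], K)[:, 0]            # (K_blocks,)
    n_blocks = resp.shape[0]
    M = m.n_samples
    coefs = np.empty((M, L + 1))
    mse = np.empty(M)
    powers = np.stack([g ** l for l in range(L + 1)], axis=2)  # (N, M, L+1)
    pred_blocks = _block_reduce(powers, K)                     # (K_blocks, M, L+1)
    for j in range(M):
        U = pred_blocks[:, j, :]                               # (K_blocks, L+1)
        mu = U.mean(axis=0)
        sd = U.std(axis=0)
        sd[0] = 1.0
        sd[sd == 0] = 1.0
        Z = (U - mu) / sd
        Z[:, 0] = 1.0
        sol, _, rank, _ = np.linalg.lstsq(Z, resp, rcond=None)
        if rank < L + 1:
            raise ValueError(
                f"singular NLT design for sample {m.sample_ids[j]!r}"
            )
        resid = resp - Z @ sol
        mse[j] = (resid ** 2).mean()
        a = sol / sd
        a[0] = sol[0] - np.sum(sol[1:] * mu[1:] / sd[1:])
        coefs[j] = a
    return PatientBiasModel(
        kind=NLT,
        order=L,
        coefficients=coefs,
        fit_block_size=K,
        weighted=False,
        residual_mse=mse,
        fitted_gene_ids=m.gene_ids,
        fitted_gene_means=m.values.mean(axis=1),
        sample_ids=m.sample_ids,
    )


def apply_nlt(m: ExpressionMatrix, model: PatientBiasModel) -> ExpressionMatrix:
    """Evaluate alpha_m entrywise at each sample's own measured values."""
    _require_log(m)
    if model.kind != NLT:
        raise ValueError("model kind must be 'nlt'")
    ids = set(m.gene_ids.astype(str))
    if ids != set(model.fitted_gene_ids.astype(str)):
        raise ValueError("model was fitted on a different gene set")
    out = np.empty_like(m.values)
    for j in range(m.n_samples):
        col = m.values[:, j]
        a = model.coefficients[j]
        out[:, j] = np.polynomial.polynomial.polyval(col, a)
        lo, hi = col.min(), col.max()
        grid = np.linspace(lo, hi, 64)
        deriv = np.polynomial.polynomial.polyval(
            grid, np.polynomial.polynomial.polyder(a)
        )
        if np.any(deriv <= 0) and np.any(deriv > 0):
            warnings.warn(
                f"alpha for sample {model.sample_ids[j]!r} is non-monotone "
                "on the observed range",
                RuntimeWarning,
                stacklevel=2,
            )
    return m.with_values(out)


def distortion_curves(
    model: PatientBiasModel, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample corrected-vs-measured curves on an expression grid.

    Returns ``(curves, deltas)``, each of shape (n_samples, len(grid)):
    for NLT the curve is alpha_m(g); for LLT it is g - beta_m(g).  The
    delta is curve - g, the per-sample scale deviation.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if model.kind not in (LLT, NLT):
        raise ValueError("distortion curves are defined for llt/nlt models")
    V = np.vander(grid, model.order + 1, increasing=True)
    poly = model.coefficients @ V.T                           # (M, G)
    curves = poly if model.kind == NLT else grid[None, :] - poly
    return curves, curves - grid[None, :]
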