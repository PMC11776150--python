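"""Reading, writing and preprocessing of expression matrices.

Preprocessing is deliberately minimal: an offset log transform
``x -> log2(x + c)`` and a mean-expression filter.  The offset c keeps
unexpressed genes (x = 0) finite; its default 0.25 is the expected value
of a nonnegative quantity uniform on [0, 0.5) that was rounded down to
zero during integer quantification.  Working on the log scale turns a
per-sample multiplicative bias b into an additive shift log2(b), up to a
distortion of order c/(bX) for a gene with true level X — see
:func:`offset_distortion_bound`.

No Z-score standardization is applied anywhere before correction: the
scale bias acts on a gene according to its mean expression level, and
dividing each gene by its own standard deviation would scramble the bias
beyond recovery.  Standardization happens only inside t statistics,
after correction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LOG2_OFFSET, RAW, ExpressionMatrix

DEFAULT_OFFSET = 0.25
DEFAULT_MEAN_THRESHOLD = 3.0  # log2 scale; log2(8) = 3 on the raw scale

_META_PREFIX = "# scale-leveler"


@dataclass
class FilterReport:
    """Bookkeeping for a mean-expression filter pass."""

    retained_gene_ids: np.ndarray
    dropped_gene_ids: np.ndarray
    threshold: float

    @property
    def n_retained(self) -> int:
        return len(self.retained_gene_ids)


def _sep_for(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_expression_matrix(path, genes_in: str = "rows") -> ExpressionMatrix:
    """Read a delimited expression table into canonical genes x samples form.

    The delimiter is chosen by extension (``.csv`` -> comma, else tab).
    A leading ``# scale-leveler`` comment line, if present, restores the
    scale/offset metadata written by :func:`write_expression_matrix`.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    sep = _sep_for(path)
    scale, offset_c = RAW, 0.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_META_PREFIX):
        for token in first[len(_META_PREFIX):].strip().split():
            key, _, val = token.partition("=")
            if key == "scale":
                scale = val
            elif key == "offset_c":
                offset_c = float(val)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     float_precision="round_trip")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if genes_in == "columns":
        df = df.T
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        scale=scale,
        offset_c=offset_c,
    )


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write genes x samples TSV/CSV with a metadata comment header.

    Round-trips through :func:`read_expression_matrix` to full printed
    precision.
    """
    sep = _sep_for(path)
    df = pd.DataFrame(m.values, index=m.gene_ids.astype(str),
                      columns=m.sample_ids.astype(str))
    try:
        with open(path, "w") as fh:
            fh.write(f"{_META_PREFIX} scale={m.scale} offset_c={m.offset_c!r}\n")
            df.to_csv(fh, sep=sep, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing expression matrix to {path}: {exc}") from exc


def log_transform(m: ExpressionMatrix, c: float = DEFAULT_OFFSET) -> ExpressionMatrix:
    """Apply the offset log transform x -> log2(x + c) entrywise."""
    if m.scale != RAW:
        raise ValueError("matrix is already log-scale")
    if c < 0:
        raise ValueError("offset c must be nonnegative")
    if c == 0 and np.any(m.values == 0):
        raise ValueError("c=0 with zero entries would produce -inf")
    return m.with_values(np.log2(m.values + c), scale=LOG2_OFFSET, offset_c=float(c))


def offset_distortion_bound(X: float, b: float = 1.0, c: float = DEFAULT_OFFSET) -> float:
    """First-order additive distortion of the offset log transform.

    For a gene with true level X measured with multiplicative bias b,
    log2(bX + c) = log2(b) + log2(X) + c/(bX) + O((c/bX)^2): the leading
    term c/(bX) is the price paid for the offset.  At X=8, b=1, c=0.25
    this is 1/32, about 3 percent.
    """
    X = float(X)
    b = float(b)
    if X <= 0 or b <= 0:
        raise ValueError("X and b must be positive")
    if c < 0:
        raise ValueError("c must be nonnegative")
    return c / (b * X)


def filter_by_mean_expression(
    m: ExpressionMatrix, threshold: float = DEFAULT_MEAN_THRESHOLD
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain genes whose across-sample mean (log2 scale) exceeds ``threshold``.

    Filtering is done once, on the log scale, before any correction.
    """
    if m.scale != LOG2_OFFSET:
        raise ValueError("filter operates on log2-offset scale matrices")
    means = m.values.mean(axis=1)
    keep = means > threshold
    if not keep.any():
        raise ValueError(
            f"all genes dropped at threshold {threshold}; lower the threshold"
        )
    report = FilterReport(
        retained_gene_ids=m.gene_ids[keep],
        dropped_gene_ids=m.gene_ids[~keep],
        threshold=float(threshold),
    )
    filtered = ExpressionMatrix(
        values=m.values[keep],
        gene_ids=m.gene_ids[keep],
        sample_ids=m.sample_ids,
        scale=m.scale,
        offset_c=m.offset_c,
    )
    return filtered, report
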