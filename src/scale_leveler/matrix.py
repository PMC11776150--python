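"""Core expression-matrix container.

The canonical in-memory object is a genes x samples matrix of expression
values together with its scale state: either ``raw`` (nonnegative counts,
TPM or FPKM) or ``log2_offset`` (values log2(x + c) for a nonnegative
offset c).  All downstream bias detection and correction operates on the
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

RAW = "raw"
LOG2_OFFSET = "log2_offset"
_SCALES = (RAW, LOG2_OFFSET)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with scale metadata.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values; no missing entries allowed.
    gene_ids : sequence of str
        Unique gene identifiers (rows).
    sample_ids : sequence of str
        Unique sample/patient identifiers (columns).
    scale : {"raw", "log2_offset"}
        Whether ``values`` are on the raw or offset-log2 scale.
    offset_c : float
        The offset c used in log2(x + c); meaningful only when
        ``scale == "log2_offset"``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    scale: str = RAW
    offset_c: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one gene and one sample")
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == RAW and np.any(self.values < 0):
            raise ValueError("raw-scale values must be nonnegative")
        if self.offset_c < 0:
            raise ValueError("offset_c must be nonnegative")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if np.any(counts > 1):
                dup = uniq[counts > 1][0]
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, **meta) -> "ExpressionMatrix":
        """Return a copy carrying new values (same ids) and optional new metadata."""
        return replace(self, values=np.asarray(values, dtype=float), **meta)

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())

    def same_genes(self, other: "ExpressionMatrix") -> bool:
        return self.n_genes == other.n_genes and bool(
            np.all(self.gene_ids.astype(str) == other.gene_ids.astype(str))
        )
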