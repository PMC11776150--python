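import numpy as np
import pytest

from scale_leveler import ExpressionMatrix


def make_log_matrix(values, gene_ids=None, sample_ids=None, offset_c=0.25):
    """Wrap a 2-D array as a log2-offset-scale ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n)]
    if sample_ids is None:
        sample_ids = [f"s{j:04d}" for j in range(m)]
    return ExpressionMatrix(values, gene_ids, sample_ids,
                            scale="log2_offset", offset_c=offset_c)


@pytest.fixture
def small_log_matrix():
    """Deterministic 50 genes x 7 samples log-scale matrix."""
    rng = np.random.default_rng(12345)
    vals = rng.uniform(3, 12, size=(50, 1)) + rng.normal(0, 0.5, size=(50, 7))
    return make_log_matrix(vals)
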