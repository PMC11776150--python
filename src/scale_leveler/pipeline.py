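"""High-level orchestration: correct, spike, resample, summarize.

These helpers wire the correction and evaluation modules together the
way a benchmarking run uses them: corrections are fitted and applied to
the unspiked matrix, spiking is injected afterwards into the corrected
values, and the spiked and matched null t statistics are computed on
the same random subpopulation split.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .correction import apply_llt, apply_nlt, fit_llt, fit_nlt, shift_correct
from .evaluation import ResamplingEnsemble, two_population_t
from .matrix import ExpressionMatrix
from .simulation import SpikeDesign, spike

METHODS = ("tpm", "shift", "llt", "nlt")


def correct_with(
    m: ExpressionMatrix, method: str, L: int = 3, K: int = 50
) -> ExpressionMatrix:
    """Apply one of the named corrections; ``tpm`` means no correction."""
    if method in ("tpm", "none"):
        return m
    if method == "shift":
        corrected, _ = shift_correct(m)
        return corrected
    if method == "llt":
        return apply_llt(m, fit_llt(m, L=L, K=K))
    if method == "nlt":
        return apply_nlt(m, fit_nlt(m, L=L, K=K))
    raise ValueError(f"unknown correction method {method!r}")


def spiking_runners(
    m: ExpressionMatrix,
    subpop_size: int,
    spike_level_percent: float,
    spiked_genes: np.ndarray | None = None,
) -> tuple[Callable, Callable]:
    """Paired per-draw t-statistic sources for ROC/ccdf ensembles.

    Each runner draws a random subpopulation of ``subpop_size`` from its
    Generator (identical per-draw Generators yield identical splits),
    computes pooled t statistics subpopulation-vs-rest, with the spiked
    runner first adding log2(1 + C/100) to the spiked genes in the
    subpopulation.
    """
    genes = (np.arange(m.n_genes) if spiked_genes is None
             else np.asarray(spiked_genes, dtype=int))
    all_idx = np.arange(m.n_samples)

    def _split(rng: np.random.Generator):
        sub = rng.choice(m.n_samples, size=subpop_size, replace=False)
        return sub, np.setdiff1d(all_idx, sub)

    def spiked_runner(rng: np.random.Generator) -> np.ndarray:
        sub, rest = _split(rng)
        if spike_level_percent > 0:
            design = SpikeDesign(subpopulation=sub, spiked_genes=genes,
                                 spike_level_percent=spike_level_percent)
            data = spike(m, design)
        else:
            data = m
        return two_population_t(data, rest, sub).t

    def null_runner(rng: np.random.Generator) -> np.ndarray:
        sub, rest = _split(rng)
        return two_population_t(m, rest, sub).t

    return spiked_runner, null_runner


def tpr_at(ensemble: ResamplingEnsemble, fpr: float) -> float:
    """Mean TPR of an ROC ensemble at (the grid point nearest) an FPR."""
    idx = int(np.argmin(np.abs(ensemble.grid - fpr)))
    return float(ensemble.mean_curve[idx])
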