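"""Matched-pair degree test for per-tissue network rewiring.

For each tissue the degrees of a shared gene list in the case-specific and
control-specific differential networks form two paired vectors; a paired
t-test on their difference quantifies how strongly the tissue's
co-expression structure was rewired, and the tissue with the smallest
p-value is called the key tissue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .networks import DifferentialNetwork

__all__ = [
    "TissueSignificance",
    "degree_vectors",
    "matched_pair_ttest",
    "compute_tissue_significance",
    "key_tissue",
]


@dataclass
class TissueSignificance:
    tissue_id: str
    t_statistic: float
    p_value: float
    n_genes: int
    degree_case: dict[str, int]
    degree_control: dict[str, int]


def degree_vectors(den: DifferentialNetwork,
                   gene_list: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Paired degree vectors over ``gene_list``; absent genes get degree 0."""
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    d1 = np.array([den.degree1.get(g, 0) for g in gene_list], dtype=int)
    d2 = np.array([den.degree2.get(g, 0) for g in gene_list], dtype=int)
    return d1, d2


def matched_pair_ttest(d1, d2) -> tuple[float, float]:
    """Paired t-test via t = sum(d) / sqrt((n*sum(d^2) - sum(d)^2)/(n-1)).

    Two-sided p on n-1 degrees of freedom.  All-zero differences return
    (0.0, 1.0) with a warning; a nonzero constant difference has zero
    variance and returns t = +/-inf with p = 0.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    n = d1.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = d1 - d2
    sum_d = float(d.sum())
    sum_d2 = float((d * d).sum())
    var_term = (n * sum_d2 - sum_d * sum_d) / (n - 1)
    if var_term <= 0.0:
        if sum_d == 0.0:
            warnings.warn("all paired differences are zero; t=0, p=1",
                          stacklevel=2)
            return 0.0, 1.0
        t = math.inf if sum_d > 0 else -math.inf
        return t, 0.0
    t = sum_d / math.sqrt(var_term)
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


def compute_tissue_significance(den: DifferentialNetwork,
                                gene_list: list[str]) -> TissueSignificance:
    """Run the paired degree test for one tissue's differential network."""
    d1, d2 = degree_vectors(den, gene_list)
    t, p = matched_pair_ttest(d1, d2)
    return TissueSignificance(
        tissue_id=den.tissue_id, t_statistic=t, p_value=p,
        n_genes=len(gene_list),
        degree_case={g: int(v) for g, v in zip(gene_list, d1)},
        degree_control={g: int(v) for g, v in zip(gene_list, d2)},
    )


def key_tissue(results: list[TissueSignificance]) -> str:
    """Tissue with minimum p; ties broken by larger |t|, then gene id order."""
    if not results:
        raise ValueError("no tissue results supplied")
    best = min(results,
               key=lambda r: (r.p_value, -abs(r.t_statistic), r.tissue_id))
    return best.tissue_id
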