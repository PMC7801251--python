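"""Tissue-to-module assignment and tissue gene-set extraction.

Each tissue is mapped to the module (column of W) with its largest loading;
the tissue's gene set is then read off the matching row of H as the genes
whose weights sit above the row mean by a configurable number of standard
deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterAssignment",
    "TissueClusterMap",
    "TissueGeneSet",
    "assign_clusters",
    "select_tissue_gene_set",
]


@dataclass
class ClusterAssignment:
    tissue_id: str
    cluster_index: int  # 1-based
    loading_weight: float
    tied: bool = False


@dataclass
class TissueClusterMap:
    entries: list[ClusterAssignment]

    def cluster_of(self, tissue_id: str) -> int:
        for e in self.entries:
            if e.tissue_id == tissue_id:
                return e.cluster_index
        raise KeyError(tissue_id)


@dataclass
class TissueGeneSet:
    """Genes characterizing one tissue, with the selection rule recorded."""

    tissue_id: str
    cluster_index: int
    gene_ids: list[str]
    weights: dict[str, float]
    threshold_rule: dict[str, float]


def assign_clusters(W: np.ndarray, tissue_ids: list[str]) -> TissueClusterMap:
    """Map each tissue row of W to its argmax module (1-based index).

    Ties are broken toward the lowest module index and flagged.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != len(tissue_ids):
        raise ValueError("W rows must match tissue_ids")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    entries = []
    for i, tissue in enumerate(tissue_ids):
        row = W[i]
        if not row.any():
            raise ValueError(f"tissue {tissue!r} has an all-zero loading row")
        j = int(np.argmax(row))
        tied = int(np.sum(row == row[j])) > 1
        entries.append(ClusterAssignment(tissue, j + 1, float(row[j]), tied))
    return TissueClusterMap(entries)


def select_tissue_gene_set(H: np.ndarray, gene_ids: list[str],
                           cluster_index: int, z_cutoff: float = 1.0,
                           tissue_id: str = "") -> TissueGeneSet:
    """Select genes with weight > row mean + z_cutoff * row sd (sample sd).

    A constant row yields an empty set with a warning.  Selected genes are
    returned in descending-weight order (ties by gene id).
    """
    H = np.asarray(H, dtype=float)
    if not 1 <= cluster_index <= H.shape[0]:
        raise ValueError(f"cluster_index {cluster_index} outside [1, {H.shape[0]}]")
    if z_cutoff < 0:
        raise ValueError("z_cutoff must be >= 0")
    if H.shape[1] != len(gene_ids):
        raise ValueError("H columns must match gene_ids")
    row = H[cluster_index - 1]
    mean = float(row.mean())
    sd = float(row.std(ddof=1)) if row.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            f"module row {cluster_index} is constant; empty gene set selected",
            stacklevel=2,
        )
        selected = np.zeros(row.size, dtype=bool)
    else:
        selected = row > mean + z_cutoff * sd
    order = sorted(np.flatnonzero(selected),
                   key=lambda i: (-row[i], gene_ids[i]))
    return TissueGeneSet(
        tissue_id=tissue_id,
        cluster_index=cluster_index,
        gene_ids=[gene_ids[i] for i in order],
        weights={gene_ids[i]: float(row[i]) for i in order},
        threshold_rule={"z_cutoff": float(z_cutoff), "row_mean": mean,
                        "row_sd": sd},
    )
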