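"""PCC co-expression networks on columns of H and their differential sets.

Genes are nodes; an undirected edge joins two genes whose module-level
profiles (columns of H, length k) are significantly correlated.  The
differential network keeps the edges present in exactly one condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConstantVectorError",
    "EdgeStats",
    "CoexpressionNetwork",
    "DifferentialNetwork",
    "pcc",
    "pcc_pvalue",
    "build_network",
    "differential_network",
]

Edge = tuple[str, str]


class ConstantVectorError(ValueError):
    """Pearson correlation undefined for a constant vector."""


def _edge(u: str, v: str) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass
class EdgeStats:
    pcc: float
    pvalue: float


@dataclass
class CoexpressionNetwork:
    condition_label: str
    tissue_id: str
    nodes: set[str]
    edges: dict[Edge, EdgeStats] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def edge_set(self) -> set[Edge]:
        return set(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass
class DifferentialNetwork:
    """Condition-specific edge sets diff1 (case-only) and diff2 (control-only)."""

    tissue_id: str
    nodes: set[str]
    diff1: dict[Edge, EdgeStats]
    diff2: dict[Edge, EdgeStats]
    degree1: dict[str, int]
    degree2: dict[str, int]


def pcc(a, b) -> float:
    """Sample Pearson correlation between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    ac = a - a.mean()
    bc = b - b.mean()
    na = float(np.linalg.norm(ac))
    nb = float(np.linalg.norm(bc))
    if na == 0.0 or nb == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = float(ac @ bc / (na * nb))
    return max(-1.0, min(1.0, r))


def pcc_pvalue(r: float, length: int) -> float:
    """Two-sided p-value for a Pearson r via the t transform, df = length-2."""
    if length < 3:
        raise ValueError("length must be >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    df = length - 2
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    t = r * np.sqrt(df / denom)
    return float(2.0 * stats.t.sf(abs(t), df))


def _pvalue_matrix(C: np.ndarray, length: int) -> np.ndarray:
    df = length - 2
    denom = np.clip(1.0 - C * C, 0.0, None)
    with np.errstate(divide="ignore"):
        t = np.abs(C) * np.sqrt(df / np.where(denom > 0, denom, np.inf))
    p = 2.0 * stats.t.sf(t, df)
    p[denom == 0.0] = 0.0
    return p


def build_network(H: np.ndarray, gene_ids: list[str], gene_set,
                  alpha: float = 0.05, tissue_id: str = "",
                  condition_label: str = "") -> CoexpressionNetwork:
    """All-pairs PCC network over ``gene_set`` columns of H.

    An edge joins genes u, v iff the two-sided p-value of their column
    correlation is below ``alpha``.  Constant columns are excluded with a
    warning; fewer than two usable genes yields an empty network.
    """
    H = np.asarray(H, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in gene_set if g not in pos]
    if missing:
        raise KeyError(f"genes absent from H columns: {sorted(missing)[:5]}")
    members = sorted(gene_set)
    cols = H[:, [pos[g] for g in members]]
    keep = cols.std(axis=0) > 0
    if not keep.all():
        dropped = [g for g, k in zip(members, keep) if not k]
        warnings.warn(
            f"{len(dropped)} constant column(s) excluded from network "
            f"({tissue_id or 'unnamed tissue'})", stacklevel=2)
        members = [g for g, k in zip(members, keep) if k]
        cols = cols[:, keep]
    net = CoexpressionNetwork(condition_label=condition_label,
                              tissue_id=tissue_id, nodes=set(members),
                              alpha=alpha)
    if len(members) < 2:
        warnings.warn("fewer than 2 usable genes; empty network", stacklevel=2)
        return net
    klen = H.shape[0]
    C = np.corrcoef(cols.T)
    C = np.clip(C, -1.0, 1.0)
    P = _pvalue_matrix(C, klen)
    iu, ju = np.triu_indices(len(members), k=1)
    sig = P[iu, ju] < alpha
    for i, j in zip(iu[sig], ju[sig]):
        e = _edge(members[i], members[j])
        net.edges[e] = EdgeStats(pcc=float(C[i, j]), pvalue=float(P[i, j]))
    return net


def differential_network(c1: CoexpressionNetwork,
                         c2: CoexpressionNetwork) -> DifferentialNetwork:
    """Edge-set differences diff1 = E1 \\ E2 and diff2 = E2 \\ E1.

    Degree maps are computed on each difference graph over the union of
    the two node sets; isolated genes get degree 0.
    """
    if c1.tissue_id != c2.tissue_id:
        raise ValueError(
            f"tissue mismatch: {c1.tissue_id!r} vs {c2.tissue_id!r}")
    nodes = c1.nodes | c2.nodes
    diff1 = {e: s for e, s in c1.edges.items() if e not in c2.edges}
    diff2 = {e: s for e, s in c2.edges.items() if e not in c1.edges}
    deg1 = {g: 0 for g in nodes}
    deg2 = {g: 0 for g in nodes}
    for u, v in diff1:
        deg1[u] += 1
        deg1[v] += 1
    for u, v in diff2:
        deg2[u] += 1
        deg2[v] += 1
    return DifferentialNetwork(tissue_id=c1.tissue_id, nodes=nodes,
                               diff1=diff1, diff2=diff2,
                               degree1=deg1, degree2=deg2)
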