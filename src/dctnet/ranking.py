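"""Anchor-relatedness scoring, per-tissue top lists, consensus, product rank.

A gene's relatedness score is the mean Pearson correlation between its
column of H and the columns of a set of known phenotype-associated anchor
genes.  Per-tissue top lists are intersected across tissues to form
consensus candidates, which can be further prioritized by the product of
their rank positions under relatedness, fold change and network degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .networks import ConstantVectorError, pcc

__all__ = [
    "AnchorSet",
    "GeneRanking",
    "ConsensusCandidates",
    "relatedness_score",
    "rank_tissue",
    "consensus_candidates",
    "composite_rank",
]


@dataclass
class AnchorSet:
    """Deduplicated, ordered set of known phenotype-associated gene ids."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = list(dict.fromkeys(self.gene_ids))
        if not self.gene_ids:
            raise ValueError("anchor set must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneRanking:
    tissue_id: str
    scores: dict[str, float]
    top_list: list[str]
    composite: dict[str, float] = field(default_factory=dict)


@dataclass
class ConsensusCandidates:
    per_tissue_top: dict[str, list[str]]
    candidates: list[str]
    tissue_counts: dict[str, int]
    mean_scores: dict[str, float]
    top_n: int
    min_tissues: int


def _anchor_columns(anchors: AnchorSet, H: np.ndarray,
                    pos: dict[str, int]) -> list[np.ndarray]:
    cols = []
    for v in anchors.gene_ids:
        if v not in pos:
            raise KeyError(f"anchor {v!r} absent from H columns")
        col = H[:, pos[v]]
        if col.std() == 0:
            warnings.warn(f"anchor {v!r} has a constant profile; skipped",
                          stacklevel=3)
            continue
        cols.append(col)
    if not cols:
        raise ValueError("all anchor profiles are constant; cannot score")
    return cols


def relatedness_score(u: str, anchors: AnchorSet, H: np.ndarray,
                      gene_ids: list[str]) -> float:
    """Mean PCC between gene u's H column and each anchor's column."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    if u not in pos:
        raise KeyError(f"gene {u!r} absent from H columns")
    cols = _anchor_columns(anchors, H, pos)
    ucol = H[:, pos[u]]
    return float(np.mean([pcc(ucol, v) for v in cols]))


def rank_tissue(H: np.ndarray, gene_ids: list[str], gene_set,
                anchors: AnchorSet, top_n: int = 30,
                tissue_id: str = "") -> GeneRanking:
    """Score every non-anchor gene in ``gene_set`` and keep the top ``top_n``.

    Descending score order, ties broken by gene id.  A gene set smaller
    than ``top_n`` returns everything with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pos = {g: i for i, g in enumerate(gene_ids)}
    anchor_ids = set(anchors.gene_ids)
    cols = _anchor_columns(anchors, H, pos)
    A = np.column_stack(cols)
    scores: dict[str, float] = {}
    for g in sorted(gene_set):
        if g in anchor_ids:
            continue
        if g not in pos:
            raise KeyError(f"gene {g!r} absent from H columns")
        ucol = H[:, pos[g]]
        if ucol.std() == 0:
            warnings.warn(f"gene {g!r} has a constant profile; unranked",
                          stacklevel=2)
            continue
        uc = ucol - ucol.mean()
        Ac = A - A.mean(axis=0)
        num = Ac.T @ uc
        den = np.linalg.norm(Ac, axis=0) * np.linalg.norm(uc)
        scores[g] = float(np.mean(np.clip(num / den, -1.0, 1.0)))
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    if len(ordered) < top_n:
        warnings.warn(
            f"gene set smaller than top_n ({len(ordered)} < {top_n}); "
            "returning all", stacklevel=2)
    return GeneRanking(tissue_id=tissue_id, scores=scores,
                       top_list=ordered[:top_n])


def consensus_candidates(rankings: list[GeneRanking],
                         min_tissues: int = 4) -> ConsensusCandidates:
    """Genes present in at least ``min_tissues`` per-tissue top lists.

    Ordered by (tissue count desc, mean score desc, gene id).
    """
    if not rankings:
        raise ValueError("no per-tissue rankings supplied")
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    per_tissue = {r.tissue_id: list(r.top_list) for r in rankings}
    counts: dict[str, int] = {}
    score_sums: dict[str, float] = {}
    for r in rankings:
        for g in r.top_list:
            counts[g] = counts.get(g, 0) + 1
            score_sums[g] = score_sums.get(g, 0.0) + r.scores[g]
    means = {g: score_sums[g] / counts[g] for g in counts}
    cands = [g for g, c in counts.items() if c >= min_tissues]
    cands.sort(key=lambda g: (-counts[g], -means[g], g))
    top_n = max(len(r.top_list) for r in rankings)
    return ConsensusCandidates(per_tissue_top=per_tissue, candidates=cands,
                               tissue_counts={g: counts[g] for g in cands},
                               mean_scores={g: means[g] for g in cands},
                               top_n=top_n, min_tissues=min_tissues)


def composite_rank(scores: dict[str, float], fc: dict[str, float],
                   degree: dict[str, int]) -> dict[str, float]:
    """Product of per-criterion rank positions (1 = best = largest value).

    Each gene is ranked independently under relatedness score, fold change
    and degree (competition ranking; ties share the better position), and
    the three positions are multiplied.  Smaller products mean higher
    priority.
    """
    genes = sorted(scores)
    for name, mapping in (("scores", scores), ("fc", fc), ("degree", degree)):
        missing = [g for g in genes if g not in mapping]
        if missing:
            raise KeyError(f"gene {missing[0]!r} missing from map {name!r}")
    out: dict[str, float] = {}
    ranks = []
    for mapping in (scores, fc, degree):
        vals = np.array([float(mapping[g]) for g in genes])
        ranks.append(stats.rankdata(-vals, method="min"))
    prod = ranks[0] * ranks[1] * ranks[2]
    for g, p in zip(genes, prod):
        out[g] = float(p)
    return out
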