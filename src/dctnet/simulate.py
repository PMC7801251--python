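"""Paired synthetic expression data with planted, fully known structure.

The generator emits case/control tissues x genes matrices built from a
shared tissue-loading matrix (so both conditions have the same tissue
correlation structure) and module-blocked gene profiles, with four planted
signals the downstream pipeline should recover:

* module membership — each background gene loads on exactly one module,
  so each tissue owns a gene set;
* anchor genes — a small group sharing a common cross-module profile in
  BOTH conditions (they are correlated with each other everywhere);
* planted candidates — genes that share the anchors' profile ONLY in the
  case condition (case-specific co-expression with the anchors), with an
  independent profile in the control;
* a rewired tissue — a subset of that tissue's module genes keeps its
  module profile in the case but is given independent profiles in the
  control, creating an excess of case-specific edges in that tissue only.

Noise is additive truncated Gaussian (clipped at zero) so the noiseless
limit is exactly low rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate_paired_dataset",
           "write_dataset"]

Edge = tuple[str, str]


def _edge(u: str, v: str) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure paired-data generator."""

    m: int = 7                      # tissues
    n: int = 500                    # genes
    k: int = 7                      # modules
    noise_sd: float = 0.1           # relative to mean signal
    n_anchors: int = 6
    n_planted_candidates: int = 10
    rewired_tissue: int | None = 3  # 0-based tissue index, or None
    n_rewired_genes: int = 10
    edge_effect: float = 0.9        # target planted pairwise correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.k * 10:
            raise ValueError("need n >= 10*k genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.edge_effect <= 1:
            raise ValueError("edge_effect must be in (0, 1]")
        if self.n_anchors + self.n_planted_candidates > self.n:
            raise ValueError("infeasible: more anchors+candidates than genes")
        if self.rewired_tissue is not None and not (
                0 <= self.rewired_tissue < self.m):
            raise ValueError("rewired_tissue outside [0, m)")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by the emitted gene ids."""

    module_membership: dict[str, int]      # background genes only
    planted_case_edges: dict[str, set[Edge]]
    planted_candidates: list[str]
    anchor_ids: list[str]
    true_R: np.ndarray
    tissue_gene_sets: dict[str, set[str]] = field(default_factory=dict)
    rewired_tissue_id: str | None = None
    rewired_gene_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "module_membership": self.module_membership,
            "planted_case_edges": {
                t: sorted([list(e) for e in es])
                for t, es in self.planted_case_edges.items()},
            "planted_candidates": self.planted_candidates,
            "anchor_ids": self.anchor_ids,
            "true_R": self.true_R.tolist(),
            "tissue_gene_sets": {t: sorted(s)
                                 for t, s in self.tissue_gene_sets.items()},
            "rewired_tissue_id": self.rewired_tissue_id,
            "rewired_gene_ids": self.rewired_gene_ids,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _anchor_profile(k: int, hi: float = 10.0, spread: float = 0.15) -> np.ndarray:
    # alternating deviations keep every coordinate's |dev|/rms small, so the
    # profile's correlation with any single-module spike stays well below
    # the edge-significance threshold
    alt = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return hi * (1.0 + spread * alt)


def generate_paired_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate (case, control, ground truth); deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.m, spec.n, spec.k
    tissue_ids = [f"T{i + 1}" for i in range(m)]
    gene_ids = [f"g{i:04d}" for i in range(n)]

    anchors = gene_ids[:spec.n_anchors]
    candidates = gene_ids[spec.n_anchors:spec.n_anchors
                          + spec.n_planted_candidates]
    background = gene_ids[spec.n_anchors + spec.n_planted_candidates:]
    module_of = {g: i % k for i, g in enumerate(background)}

    # shared tissue loadings: diagonal-dominant, identical in both conditions
    W = 0.15 * rng.uniform(0.5, 1.0, size=(m, k))
    for i in range(m):
        W[i, i % k] = 1.0

    p = _anchor_profile(k)
    sd_p = float(p.std())
    # each planted column is p + independent noise; two such columns then
    # correlate at 1/(1+tau^2), so this tau hits edge_effect pairwise
    tau = np.sqrt(1.0 / spec.edge_effect - 1.0)

    H1 = np.zeros((k, n))
    H2 = np.zeros((k, n))
    idx = {g: i for i, g in enumerate(gene_ids)}

    rewired: list[str] = []
    rewired_tissue_id = None
    if spec.rewired_tissue is not None:
        rewired_tissue_id = tissue_ids[spec.rewired_tissue]
        module_r = spec.rewired_tissue % k
        pool = [g for g in background if module_of[g] == module_r]
        rewired = pool[:spec.n_rewired_genes]

    for g in background:
        j = module_of[g]
        col = rng.uniform(0.0, 0.4, size=k)
        col[j] = rng.uniform(8.0, 12.0)
        H1[:, idx[g]] = col
        if g in rewired:
            # low, unstructured control profile: the gene loses its module
            # co-expression in the control without joining other tissues'
            # gene sets
            H2[:, idx[g]] = rng.uniform(0.05, 0.45, size=k)
        else:
            H2[:, idx[g]] = col

    for g in anchors:
        col = rng.uniform(0.8, 1.2) * (p + rng.normal(0.0, sd_p * tau, size=k))
        col = np.clip(col, 0.1, None)
        H1[:, idx[g]] = col
        H2[:, idx[g]] = col

    for g in candidates:
        col = rng.uniform(0.8, 1.2) * (p + rng.normal(0.0, sd_p * tau, size=k))
        H1[:, idx[g]] = np.clip(col, 0.1, None)
        H2[:, idx[g]] = rng.uniform(5.0, 15.0, size=k)

    S1 = W @ H1
    S2 = W @ H2
    mean_signal = float((S1.mean() + S2.mean()) / 2.0)
    sd = spec.noise_sd * mean_signal
    X1 = np.clip(S1 + rng.normal(0.0, sd, size=S1.shape) if sd > 0 else S1,
                 0.0, None)
    X2 = np.clip(S2 + rng.normal(0.0, sd, size=S2.shape) if sd > 0 else S2,
                 0.0, None)

    # conserved tissue correlation of the noiseless signals
    C1 = np.corrcoef(S1)
    C2 = np.corrcoef(S2)
    true_R = np.clip((C1 + C2) / 2.0, 0.0, 1.0)
    np.fill_diagonal(true_R, 1.0)

    shared = [*anchors, *candidates]
    tissue_gene_sets = {
        tissue_ids[i]: {g for g in background if module_of[g] == i % k}
        | set(shared)
        for i in range(m)
    }

    # planted case-specific pairs: candidate-anchor and candidate-candidate
    # everywhere (anchor-anchor pairs are conserved, hence excluded), plus
    # rewired-gene pairs inside the rewired tissue
    base_edges: set[Edge] = set()
    for i, u in enumerate(candidates):
        for v in anchors:
            base_edges.add(_edge(u, v))
        for v in candidates[i + 1:]:
            base_edges.add(_edge(u, v))
    planted: dict[str, set[Edge]] = {t: set(base_edges) for t in tissue_ids}
    if rewired:
        module_r = spec.rewired_tissue % k
        mates = [g for g in background
                 if module_of[g] == module_r and g not in rewired]
        extra = planted[rewired_tissue_id]
        for i, u in enumerate(rewired):
            for v in mates:
                extra.add(_edge(u, v))
            for v in rewired[i + 1:]:
                extra.add(_edge(u, v))

    truth = GroundTruth(
        module_membership=module_of,
        planted_case_edges=planted,
        planted_candidates=list(candidates),
        anchor_ids=list(anchors),
        true_R=true_R,
        tissue_gene_sets=tissue_gene_sets,
        rewired_tissue_id=rewired_tissue_id,
        rewired_gene_ids=list(rewired),
    )
    case = ExpressionMatrix("case", tissue_ids, gene_ids, X1)
    control = ExpressionMatrix("control", tissue_ids, gene_ids, X2)
    return case, control, truth


def write_dataset(spec: SyntheticSpec, outdir: str | Path,
                  n_nominal_tfs: int = 20) -> None:
    """Write case/control tables, gene lists and ground truth under outdir.

    A nominal TF list (a deterministic sample of background genes) is
    included so the directory is directly consumable by the pipeline.
    """
    from .io import write_expression_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    case, control, truth = generate_paired_dataset(spec)
    write_expression_table(case, outdir / "case.tsv")
    write_expression_table(control, outdir / "control.tsv")
    (outdir / "anchors.txt").write_text(
        "# anchor genes\n" + "\n".join(truth.anchor_ids) + "\n")
    background = sorted(truth.module_membership)
    step = max(1, len(background) // max(n_nominal_tfs, 1))
    tfs = background[::step][:n_nominal_tfs]
    (outdir / "tfs.txt").write_text(
        "# nominal transcription factors\n" + "\n".join(tfs) + "\n")
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    (outdir / "generator_params.json").write_text(
        json.dumps(asdict(spec), indent=2, sort_keys=True) + "\n")
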