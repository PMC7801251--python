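"""End-to-end orchestration: data -> factorization -> networks -> candidates.

The stages run in a fixed order: feature-gene assembly, conserved-correlation
estimation, paired factorization, per-tissue module/gene-set extraction,
co-expression and differential networks, anchor-relatedness ranking with
cross-tissue consensus, and the matched-pair degree test that names the key
tissue.  All randomness flows from a single seed and outputs are written as
plain TSV/JSON so identical configurations yield byte-identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from . import factorization as fz
from . import modules as tm
from . import networks as nw
from . import ranking as rk
from . import significance as sg

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("dctnet")


@dataclass
class RunConfig:
    """Paths, parameters and flags for one pipeline run."""

    case_path: str = ""
    control_path: str = ""
    tf_list_path: str = ""
    anchor_list_path: str = ""
    outdir: str | None = None

    fc_cutoff: float = 1.2
    pseudocount: float = 0.1
    k: int | None = None            # None -> number of tissues
    lambda_: float = 1.0
    mode: str = "soft"
    alpha: float = 0.05
    z_cutoff: float = 1.0
    top_n: int = 30
    min_tissues: int = 4
    seed: int = 0
    restarts: int = 5
    max_iter: int = 5000
    tol: float = 1e-6

    score_side: str = "case"        # case | control | diff
    degree_genes: str = "all"       # all | tf | anchors | deg
    degree_source: str = "diff"     # diff | full
    edge_fdr: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("soft", "hard", "none"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.score_side not in ("case", "control", "diff"):
            raise ValueError(f"invalid score_side {self.score_side!r}")
        if self.degree_genes not in ("all", "tf", "anchors", "deg"):
            raise ValueError(f"invalid degree_genes {self.degree_genes!r}")
        if self.degree_source not in ("diff", "full"):
            raise ValueError(f"invalid degree_source {self.degree_source!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_tissues < 1 or self.top_n < 1:
            raise ValueError("min_tissues and top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    catalog: dio.FeatureGeneCatalog
    conserved: fz.ConservedCorrelation
    fit: fz.FactorizationResult
    clusters_case: tm.TissueClusterMap
    clusters_control: tm.TissueClusterMap
    tissue_gene_sets: dict[str, set[str]]
    networks_case: dict[str, nw.CoexpressionNetwork]
    networks_control: dict[str, nw.CoexpressionNetwork]
    differential: dict[str, nw.DifferentialNetwork]
    rankings: dict[str, rk.GeneRanking]
    consensus: rk.ConsensusCandidates
    composite: dict[str, float]
    significance: list[sg.TissueSignificance]
    key_tissue: str
    report: dict = field(default_factory=dict)


def _apply_fdr(net: nw.CoexpressionNetwork, alpha: float) -> None:
    """Benjamini-Hochberg filter over the computed edge p-values, in place."""
    from scipy.stats import false_discovery_control

    if not net.edges:
        return
    items = sorted(net.edges.items())
    pvals = [s.pvalue for _, s in items]
    adj = false_discovery_control(pvals, method="bh")
    net.edges = {e: s for (e, s), q in zip(items, adj) if q < alpha}


def run_pipeline(config: RunConfig,
                 case: dio.ExpressionMatrix | None = None,
                 control: dio.ExpressionMatrix | None = None,
                 tf_ids: list[str] | None = None,
                 anchor_ids: list[str] | None = None) -> PipelineResult:
    """Execute the full analysis; matrices may be passed in memory.

    When ``config.outdir`` is set, every stage's tables plus a JSON run
    report are written beneath it.
    """
    t0 = time.perf_counter()
    stage = "data_io"
    try:
        if case is None:
            case = dio.load_expression_table(config.case_path, "case")
        if control is None:
            control = dio.load_expression_table(config.control_path, "control")
        if tf_ids is None:
            tf_ids = (dio.load_gene_list(config.tf_list_path)
                      if config.tf_list_path else [])
        if anchor_ids is None:
            anchor_ids = dio.load_gene_list(config.anchor_list_path)
        if control.tissue_ids != case.tissue_ids:
            control = control.reorder_tissues(case.tissue_ids)
        if control.gene_ids != case.gene_ids:
            control = control.subset_genes(case.gene_ids)
        if config.min_tissues > case.n_tissues:
            raise ValueError(
                f"min_tissues={config.min_tissues} exceeds the "
                f"{case.n_tissues} available tissues")

        fc = dio.max_fold_change(case, control, config.pseudocount)
        catalog = dio.assemble_feature_genes(
            fc, config.fc_cutoff, tf_ids, anchor_ids)
        case_f = case.subset_genes(catalog.feature_ids)
        control_f = control.subset_genes(catalog.feature_ids)
        log.info("stage %-18s %6.2fs  (%d feature genes)", stage,
                 time.perf_counter() - t0, len(catalog.feature_ids))

        stage = "jcnmf_core"
        t1 = time.perf_counter()
        conserved = fz.estimate_conserved_correlation(case_f, control_f)
        k = config.k if config.k is not None else case.n_tissues
        fit = fz.jcnmf_fit(case_f, control_f, k=k, lambda_=config.lambda_,
                           mode=config.mode, max_iter=config.max_iter,
                           tol=config.tol, seed=config.seed,
                           n_restarts=config.restarts, R=conserved)
        log.info("stage %-18s %6.2fs  (objective %.4g, residual %.4g)",
                 stage, time.perf_counter() - t1, fit.objective,
                 fit.constraint_residual)

        stage = "tissue_modules"
        t1 = time.perf_counter()
        tissues = case.tissue_ids
        genes = catalog.feature_ids
        clusters1 = tm.assign_clusters(fit.W1, tissues)
        clusters2 = tm.assign_clusters(fit.W2, tissues)
        gene_sets: dict[str, set[str]] = {}
        for tissue in tissues:
            s1 = tm.select_tissue_gene_set(
                fit.H1, genes, clusters1.cluster_of(tissue),
                config.z_cutoff, tissue)
            s2 = tm.select_tissue_gene_set(
                fit.H2, genes, clusters2.cluster_of(tissue),
                config.z_cutoff, tissue)
            # union keeps the case and control edge sets comparable
            gene_sets[tissue] = set(s1.gene_ids) | set(s2.gene_ids)
        log.info("stage %-18s %6.2fs", stage, time.perf_counter() - t1)

        stage = "coexpr_networks"
        t1 = time.perf_counter()
        nets1, nets2, dens = {}, {}, {}
        for tissue in tissues:
            c1 = nw.build_network(fit.H1, genes, gene_sets[tissue],
                                  config.alpha, tissue, "case")
            c2 = nw.build_network(fit.H2, genes, gene_sets[tissue],
                                  config.alpha, tissue, "control")
            if config.edge_fdr:
                _apply_fdr(c1, config.alpha)
                _apply_fdr(c2, config.alpha)
            nets1[tissue], nets2[tissue] = c1, c2
            dens[tissue] = nw.differential_network(c1, c2)
        log.info("stage %-18s %6.2fs", stage, time.perf_counter() - t1)

        stage = "candidate_ranking"
        t1 = time.perf_counter()
        anchors = rk.AnchorSet(sorted(catalog.anchor_ids))
        H_score = fit.H2 if config.score_side == "control" else fit.H1
        rankings: dict[str, rk.GeneRanking] = {}
        for tissue in tissues:
            pool = set(gene_sets[tissue])
            if config.score_side == "diff":
                adj = {g for (u, v) in dens[tissue].diff1 for g in (u, v)}
                near_anchor = {g for (u, v) in dens[tissue].diff1
                               for g in (u, v)
                               if u in anchors or v in anchors}
                pool &= (near_anchor or adj)
            rankings[tissue] = rk.rank_tissue(
                H_score, genes, pool, anchors, config.top_n, tissue)
        consensus = rk.consensus_candidates(
            list(rankings.values()), config.min_tissues)
        composite: dict[str, float] = {}
        if consensus.candidates:
            total_deg = {g: 0 for g in consensus.candidates}
            for den in dens.values():
                for g in total_deg:
                    total_deg[g] += den.degree1.get(g, 0)
            composite = rk.composite_rank(
                {g: consensus.mean_scores[g] for g in consensus.candidates},
                {g: catalog.per_gene_max_fc[g] for g in consensus.candidates},
                total_deg)
        log.info("stage %-18s %6.2fs  (%d consensus candidates)",
                 stage, time.perf_counter() - t1, len(consensus.candidates))

        stage = "tissue_significance"
        t1 = time.perf_counter()
        class_pool = {
            "all": None,
            "tf": catalog.tf_ids,
            "anchors": catalog.anchor_ids,
            "deg": catalog.deg_ids,
        }[config.degree_genes]
        sig: list[sg.TissueSignificance] = []
        for tissue in tissues:
            if config.degree_source == "full":
                d1map = nets1[tissue].degree()
                d2map = nets2[tissue].degree()
                nodes = set(d1map) | set(d2map)
                den = dens[tissue]
                den = nw.DifferentialNetwork(
                    tissue_id=tissue, nodes=nodes,
                    diff1=nets1[tissue].edges, diff2=nets2[tissue].edges,
                    degree1={g: d1map.get(g, 0) for g in nodes},
                    degree2={g: d2map.get(g, 0) for g in nodes})
            else:
                den = dens[tissue]
            gene_list = sorted(den.nodes if class_pool is None
                               else den.nodes & set(class_pool))
            if not gene_list:
                log.warning("tissue %s: no genes in degree class %r; skipped",
                            tissue, config.degree_genes)
                continue
            sig.append(sg.compute_tissue_significance(den, gene_list))
        key = sg.key_tissue(sig)
        log.info("stage %-18s %6.2fs  (key tissue %s)",
                 stage, time.perf_counter() - t1, key)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report = _build_report(config, catalog, fit, consensus, composite, sig, key)
    result = PipelineResult(
        config=config, catalog=catalog, conserved=conserved, fit=fit,
        clusters_case=clusters1, clusters_control=clusters2,
        tissue_gene_sets=gene_sets, networks_case=nets1,
        networks_control=nets2, differential=dens, rankings=rankings,
        consensus=consensus, composite=composite, significance=sig,
        key_tissue=key, report=report)
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return result


def _build_report(config, catalog, fit, consensus, composite, sig, key) -> dict:
    from . import __version__

    return {
        "dctnet_version": __version__,
        "config": config.to_dict(),
        "n_feature_genes": len(catalog.feature_ids),
        "n_deg": len(catalog.deg_ids),
        "n_tf": len(catalog.tf_ids),
        "n_anchors": len(catalog.anchor_ids),
        "factorization": {
            "k": fit.k,
            "mode": fit.mode,
            "lambda": fit.lambda_,
            "seed": fit.seed,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "final_objective": fit.objective,
            "constraint_residual": fit.constraint_residual,
        },
        "candidates": list(consensus.candidates),
        "candidate_tissue_counts": consensus.tissue_counts,
        "composite_rank": composite,
        "tissue_pvalues": {s.tissue_id: s.p_value for s in sig},
        "key_tissue": key,
    }


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_feature_catalog(res.catalog, outdir / "feature_genes.tsv")
    pd.DataFrame(res.conserved.R, index=res.conserved.tissue_ids,
                 columns=res.conserved.tissue_ids).to_csv(
        outdir / "conserved_correlation.tsv", sep="\t", float_format="%.10g")
    res.fit.write(outdir / "factorization")

    rows = []
    for label, cmap in (("case", res.clusters_case),
                        ("control", res.clusters_control)):
        for e in cmap.entries:
            rows.append({"condition": label, "tissue_id": e.tissue_id,
                         "cluster_index": e.cluster_index,
                         "loading_weight": e.loading_weight, "tied": e.tied})
    pd.DataFrame(rows).to_csv(outdir / "tissue_clusters.tsv", sep="\t",
                              index=False, float_format="%.10g")

    rows = [{"tissue_id": t, "gene_id": g}
            for t in sorted(res.tissue_gene_sets)
            for g in sorted(res.tissue_gene_sets[t])]
    pd.DataFrame(rows).to_csv(outdir / "tissue_gene_sets.tsv", sep="\t",
                              index=False)

    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    for tissue, den in sorted(res.differential.items()):
        rows = []
        for label, nets in (("case", res.networks_case),
                            ("control", res.networks_control)):
            for (u, v), s in sorted(nets[tissue].edges.items()):
                rows.append({"gene_u": u, "gene_v": v, "pcc": s.pcc,
                             "pvalue": s.pvalue, "condition": label,
                             "tissue": tissue})
        pd.DataFrame(rows).to_csv(netdir / f"{tissue}_edges.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        rows = []
        for side, edges in (("case_specific", den.diff1),
                            ("control_specific", den.diff2)):
            for (u, v), s in sorted(edges.items()):
                rows.append({"gene_u": u, "gene_v": v, "pcc": s.pcc,
                             "pvalue": s.pvalue, "diff_side": side,
                             "tissue": tissue})
        pd.DataFrame(rows).to_csv(netdir / f"{tissue}_diff.tsv", sep="\t",
                                  index=False, float_format="%.10g")

    rankdir = outdir / "rankings"
    rankdir.mkdir(exist_ok=True)
    for tissue, r in sorted(res.rankings.items()):
        rows = [{"gene_id": g, "R_score": r.scores[g], "rank": i + 1}
                for i, g in enumerate(r.top_list)]
        pd.DataFrame(rows).to_csv(rankdir / f"{tissue}_ranking.tsv", sep="\t",
                                  index=False, float_format="%.10g")

    rows = [{"gene_id": g,
             "tissue_count": res.consensus.tissue_counts[g],
             "mean_R": res.consensus.mean_scores[g],
             "composite_product": res.composite.get(g, float("nan"))}
            for g in res.consensus.candidates]
    pd.DataFrame(rows).to_csv(outdir / "consensus_candidates.tsv", sep="\t",
                              index=False, float_format="%.10g")

    rows = [{"tissue_id": s.tissue_id, "n_genes": s.n_genes,
             "t": s.t_statistic, "p": s.p_value}
            for s in res.significance]
    pd.DataFrame(rows).to_csv(outdir / "tissue_significance.tsv", sep="\t",
                              index=False, float_format="%.10g")

    (outdir / "report.json").write_text(
        json.dumps(res.report, indent=2, sort_keys=True) + "\n")
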