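"""Expression-table / gene-list I/O, fold changes, and feature-gene assembly.

Expression tables on disk are delimited text with genes as rows: the first
column holds gene identifiers, the header row holds tissue names, and the
body is numeric (FPKM-like, nonnegative).  In memory the matrix is kept
tissues x genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FeatureGeneCatalog",
    "FormatError",
    "DomainError",
    "AlignmentError",
    "load_expression_table",
    "write_expression_table",
    "load_gene_list",
    "max_fold_change",
    "assemble_feature_genes",
    "write_feature_catalog",
]


class FormatError(ValueError):
    """Malformed expression table or gene list."""


class DomainError(ValueError):
    """Values outside the admissible domain (negative / non-finite FPKM)."""


class AlignmentError(ValueError):
    """Mismatched gene or tissue sets between paired matrices."""


@dataclass
class ExpressionMatrix:
    """Tissues x genes nonnegative expression values for one condition.

    Attributes
    ----------
    condition_label : str
        Free-text label for the condition (e.g. ``"case"``).
    tissue_ids : list of str
        Ordered tissue names (rows of ``values``).
    gene_ids : list of str
        Ordered gene identifiers (columns of ``values``).
    values : ndarray of shape (n_tissues, n_genes)
        Nonnegative, finite expression values.
    """

    condition_label: str
    tissue_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.tissue_ids = [str(t) for t in self.tissue_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.tissue_ids), len(self.gene_ids)):
            raise FormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.tissue_ids)} tissues x {len(self.gene_ids)} genes"
            )
        if len(set(self.tissue_ids)) != len(self.tissue_ids):
            raise FormatError("duplicate tissue names")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("expression values must be finite")
        if np.any(self.values < 0):
            raise DomainError("expression values must be nonnegative")

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def reorder_tissues(self, tissue_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy with rows re-ordered to match ``tissue_ids``."""
        if set(tissue_ids) != set(self.tissue_ids):
            raise AlignmentError("tissue sets differ; cannot reorder")
        pos = {t: i for i, t in enumerate(self.tissue_ids)}
        idx = [pos[t] for t in tissue_ids]
        return ExpressionMatrix(
            self.condition_label, list(tissue_ids), list(self.gene_ids),
            self.values[idx, :].copy(),
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        pos = self.gene_index()
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            self.condition_label, list(self.tissue_ids), list(gene_ids),
            self.values[:, idx].copy(),
        )


@dataclass
class FeatureGeneCatalog:
    """The DEG/TF/anchor partition whose union defines the columns of X."""

    deg_ids: set[str]
    tf_ids: set[str]
    anchor_ids: set[str]
    feature_ids: list[str]
    per_gene_max_fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("feature_ids contain duplicates")
        if set(self.feature_ids) != (self.deg_ids | self.tf_ids | self.anchor_ids):
            raise FormatError("feature_ids must equal the union of deg/tf/anchor sets")

    def source_flags(self, gene: str) -> str:
        flags = []
        if gene in self.deg_ids:
            flags.append("deg")
        if gene in self.tf_ids:
            flags.append("tf")
        if gene in self.anchor_ids:
            flags.append("anchor")
        return "|".join(flags)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_expression_table(path: str | Path, condition_label: str) -> ExpressionMatrix:
    """Parse a genes-as-rows delimited table into an :class:`ExpressionMatrix`.

    The first column must hold gene identifiers and the header row tissue
    names.  The matrix is transposed internally to tissues x genes.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no tissue columns found")
    # a fully numeric header row almost certainly means the header is missing
    numeric_header = all(_parses_as_number(str(c)) for c in df.columns)
    if numeric_header:
        raise FormatError(f"{path}: header row of tissue names is missing")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene identifiers {dups[:5]}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.columns[body.isna().any()].tolist()
        raise FormatError(f"{path}: non-numeric cells in columns {bad[:5]}")
    if (body.values < 0).any():
        raise DomainError(f"{path}: negative expression values")
    return ExpressionMatrix(
        condition_label=condition_label,
        tissue_ids=[str(c) for c in df.columns],
        gene_ids=[str(g) for g in df.index],
        values=body.values.T.astype(float),
    )


def _parses_as_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           float_format: str = "%.10g") -> None:
    """Write a matrix back to disk in the genes-as-rows format of the loader."""
    path = Path(path)
    df = pd.DataFrame(matrix.values.T, index=matrix.gene_ids,
                      columns=matrix.tissue_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)


def load_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list; '#' lines are comments."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token not in seen:
            seen.add(token)
            out.append(token)
    return out


def max_fold_change(case: ExpressionMatrix, control: ExpressionMatrix,
                    pseudocount: float = 0.1) -> dict[str, float]:
    """Per-gene maximum fold change across tissues, direction-symmetric.

    For gene g the value is ``max_t max(r, 1/r)`` with
    ``r = (case[t,g]+pseudocount) / (control[t,g]+pseudocount)``; always >= 1.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(case.gene_ids) != set(control.gene_ids):
        raise AlignmentError("case and control gene sets differ")
    if set(case.tissue_ids) != set(control.tissue_ids):
        raise AlignmentError("case and control tissue sets differ")
    ctrl = control
    if control.tissue_ids != case.tissue_ids:
        ctrl = control.reorder_tissues(case.tissue_ids)
    if ctrl.gene_ids != case.gene_ids:
        ctrl = ctrl.subset_genes(case.gene_ids)
    r = (case.values + pseudocount) / (ctrl.values + pseudocount)
    fc = np.max(np.maximum(r, 1.0 / r), axis=0)
    return dict(zip(case.gene_ids, fc.astype(float)))


def assemble_feature_genes(fc: dict[str, float], fc_cutoff: float = 1.2,
                           tf_ids: list[str] | set[str] = (),
                           anchor_ids: list[str] | set[str] = ()) -> FeatureGeneCatalog:
    """Build the feature-gene catalog: fold-change DEGs + TFs + anchors.

    DEGs are genes whose max fold change meets ``fc_cutoff`` (inclusive).
    TFs and anchors are included regardless of their expression change, but
    must be present in the expression matrices (keys of ``fc``); absent TFs
    are dropped with a warning, absent anchors are a hard error because the
    ranking stage cannot run without them.
    """
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    tf_list = list(dict.fromkeys(tf_ids))
    anchor_list = list(dict.fromkeys(anchor_ids))
    missing_anchors = [a for a in anchor_list if a not in fc]
    if missing_anchors:
        raise AlignmentError(
            f"anchor genes absent from expression matrices: {missing_anchors}"
        )
    missing_tfs = [t for t in tf_list if t not in fc]
    if missing_tfs:
        warnings.warn(
            f"{len(missing_tfs)} TF ids absent from expression matrices; dropped",
            stacklevel=2,
        )
        tf_list = [t for t in tf_list if t in fc]
    deg = [g for g, v in fc.items() if v >= fc_cutoff]
    feature: list[str] = []
    seen: set[str] = set()
    for g in [*deg, *tf_list, *anchor_list]:
        if g not in seen:
            seen.add(g)
            feature.append(g)
    return FeatureGeneCatalog(
        deg_ids=set(deg),
        tf_ids=set(tf_list),
        anchor_ids=set(anchor_list),
        feature_ids=feature,
        per_gene_max_fc={g: float(fc[g]) for g in feature},
    )


def write_feature_catalog(catalog: FeatureGeneCatalog, path: str | Path) -> None:
    rows = [
        {
            "gene_id": g,
            "source_flags": catalog.source_flags(g),
            "max_fold_change": catalog.per_gene_max_fc.get(g, float("nan")),
        }
        for g in catalog.feature_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
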