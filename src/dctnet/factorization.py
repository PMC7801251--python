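"""Paired NMF solvers and estimation of the conserved tissue correlation.

Three factorization modes are provided for a pair of tissues x genes
matrices X1, X2:

``soft``
    minimizes  ||X1 - W1 H1||_F^2 + ||X2 - W2 H2||_F^2
             + lambda * (||W1 W1' - R||_F^2 + ||W2 W2' - R||_F^2)
    where R is the conserved tissue-correlation matrix estimated from the
    data and held fixed.  Both conditions are thereby pulled toward the
    same tissue Gram structure without forcing W1 = W2.
``hard``
    a single shared W fitted on the concatenated matrix [X1 X2], so
    W1 and W2 are literally the same factor.
``none``
    two independent classical NMFs.

All modes use multiplicative updates that preserve nonnegativity exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, AlignmentError

__all__ = [
    "ConservedCorrelation",
    "FactorizationResult",
    "estimate_conserved_correlation",
    "jcnmf_fit",
]

_EPS = 1e-12


@dataclass
class ConservedCorrelation:
    """Symmetric tissue x tissue correlation target with unit diagonal."""

    tissue_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.tissue_ids)
        if self.R.shape != (m, m):
            raise ValueError("R shape inconsistent with tissue_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if np.any(self.R < 0) or np.any(self.R > 1 + 1e-12):
            raise ValueError("R entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have unit diagonal")


@dataclass
class FactorizationResult:
    """Fitted paired factors plus diagnostics.

    ``W1, W2`` are tissues x modules loadings, ``H1, H2`` modules x genes
    levels.  ``constraint_residual`` is ``||W1 W1' - W2 W2'||_F``.
    """

    W1: np.ndarray
    W2: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    k: int
    mode: str
    lambda_: float
    objective_trace: list[float]
    constraint_residual: float
    seed: int
    n_iter: int
    converged: bool
    R: np.ndarray | None = None
    tissue_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def reconstruction_error(self, X1: np.ndarray, X2: np.ndarray) -> float:
        """Relative Frobenius reconstruction error over both conditions."""
        num = math.sqrt(
            np.linalg.norm(X1 - self.W1 @ self.H1) ** 2
            + np.linalg.norm(X2 - self.W2 @ self.H2) ** 2
        )
        den = math.sqrt(np.linalg.norm(X1) ** 2 + np.linalg.norm(X2) ** 2)
        return num / den

    def write(self, outdir: str | Path) -> None:
        """Write W/H factors as TSV and run metadata as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mods = [f"M{j + 1}" for j in range(self.k)]
        for name, mat in (("W1", self.W1), ("W2", self.W2)):
            pd.DataFrame(mat, index=self.tissue_ids or None, columns=mods).to_csv(
                outdir / f"{name}.tsv", sep="\t", float_format="%.10g")
        for name, mat in (("H1", self.H1), ("H2", self.H2)):
            pd.DataFrame(mat, index=mods, columns=self.gene_ids or None).to_csv(
                outdir / f"{name}.tsv", sep="\t", float_format="%.10g")
        meta = {
            "k": self.k,
            "mode": self.mode,
            "lambda": self.lambda_,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "final_objective": self.objective,
            "constraint_residual": self.constraint_residual,
        }
        (outdir / "factorization.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _tissue_pcc(values: np.ndarray, tissue_ids: list[str]) -> np.ndarray:
    sd = values.std(axis=1)
    flat = [tissue_ids[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(
            f"tissue(s) with zero variance across genes: {flat}; "
            "Pearson correlation undefined"
        )
    return np.corrcoef(values)


def estimate_conserved_correlation(
    X1: ExpressionMatrix, X2: ExpressionMatrix
) -> ConservedCorrelation:
    """Average the two tissue-level PCC matrices and clip negatives to zero.

    R = clip0( (PCC_rows(X1) + PCC_rows(X2)) / 2 ), diagonal forced to 1.
    Negative tissue correlations are clipped so R stays nonnegative, which
    the multiplicative solver requires.
    """
    if X1.tissue_ids != X2.tissue_ids:
        raise AlignmentError("tissue orderings differ between conditions")
    if X1.gene_ids != X2.gene_ids:
        raise AlignmentError("gene orderings differ between conditions")
    C1 = _tissue_pcc(X1.values, X1.tissue_ids)
    C2 = _tissue_pcc(X2.values, X2.tissue_ids)
    R = np.clip((C1 + C2) / 2.0, 0.0, 1.0)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return ConservedCorrelation(tissue_ids=list(X1.tissue_ids), R=R)


def _init_factors(rng: np.random.Generator, X: np.ndarray, k: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    m, n = X.shape
    scale = math.sqrt(max(X.mean(), _EPS) / k)
    # uniform over (0, 1] so no factor entry starts at an absorbing zero
    W = (1.0 - rng.random((m, k))) * scale
    H = (1.0 - rng.random((k, n))) * scale
    return W, H


def _objective_one(X: np.ndarray, W: np.ndarray, H: np.ndarray,
                   lam: float, R: np.ndarray | None) -> float:
    obj = float(np.linalg.norm(X - W @ H) ** 2)
    if lam > 0 and R is not None:
        obj += lam * float(np.linalg.norm(W @ W.T - R) ** 2)
    return obj


def _update_h(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    return H * (W.T @ X) / (W.T @ W @ H + _EPS)


def _update_w(X: np.ndarray, W: np.ndarray, H: np.ndarray,
              lam: float, R: np.ndarray | None) -> np.ndarray:
    HHt = H @ H.T
    num = X @ H.T
    den = W @ HHt
    if lam > 0 and R is not None:
        num = num + 2.0 * lam * (R @ W)
        den = den + 2.0 * lam * (W @ (W.T @ W))
    return W * num / (den + _EPS)


def _update_w_monotone(X: np.ndarray, W: np.ndarray, H: np.ndarray,
                       lam: float, R: np.ndarray | None,
                       current_obj: float) -> tuple[np.ndarray, float]:
    """W step with a damping safeguard for the quartic Gram penalty.

    The plain multiplicative step is not provably monotone once the
    lam * ||W W' - R||^2 term is active; if the objective increases the
    multiplicative ratio is raised to a shrinking power (ratio -> 1 leaves
    W unchanged), so the trace is non-increasing by construction.
    """
    W_new = _update_w(X, W, H, lam, R)
    if lam == 0 or R is None:
        return W_new, _objective_one(X, W_new, H, lam, R)
    obj_new = _objective_one(X, W_new, H, lam, R)
    if obj_new <= current_obj:
        return W_new, obj_new
    ratio = W_new / np.maximum(W, _EPS)
    eta = 0.5
    for _ in range(40):
        W_try = W * np.power(ratio, eta)
        obj_try = _objective_one(X, W_try, H, lam, R)
        if obj_try <= current_obj:
            return W_try, obj_try
        eta *= 0.5
    return W, current_obj


def _fit_pair(X1: np.ndarray, X2: np.ndarray, k: int, lam: float,
              R: np.ndarray | None, rng: np.random.Generator,
              max_iter: int, tol: float):
    # one shared starting point for both conditions: the two trajectories
    # then land in aligned module bases, so condition-specific differences
    # in the fitted factors reflect the data rather than the initialization
    W1, H1 = _init_factors(rng, (X1 + X2) / 2.0, k)
    W2, H2 = W1.copy(), H1.copy()
    obj1 = _objective_one(X1, W1, H1, lam, R)
    obj2 = _objective_one(X2, W2, H2, lam, R)
    trace = [obj1 + obj2]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        H1 = _update_h(X1, W1, H1)
        obj1 = _objective_one(X1, W1, H1, lam, R)
        W1, obj1 = _update_w_monotone(X1, W1, H1, lam, R, obj1)
        H2 = _update_h(X2, W2, H2)
        obj2 = _objective_one(X2, W2, H2, lam, R)
        W2, obj2 = _update_w_monotone(X2, W2, H2, lam, R, obj2)
        total = obj1 + obj2
        trace.append(total)
        n_iter = it
        prev = trace[-2]
        if prev > 0 and abs(prev - total) / prev < tol:
            converged = True
            break
    return W1, H1, W2, H2, trace, n_iter, converged


def _fit_hard(X1: np.ndarray, X2: np.ndarray, k: int,
              rng: np.random.Generator, max_iter: int, tol: float):
    n = X1.shape[1]
    Xc = np.hstack([X1, X2])
    W, Hc = _init_factors(rng, Xc, k)
    trace = [_objective_one(Xc, W, Hc, 0.0, None)]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        Hc = _update_h(Xc, W, Hc)
        W = _update_w(Xc, W, Hc, 0.0, None)
        total = _objective_one(Xc, W, Hc, 0.0, None)
        trace.append(total)
        n_iter = it
        prev = trace[-2]
        if prev > 0 and abs(prev - total) / prev < tol:
            converged = True
            break
    return W, Hc[:, :n], Hc[:, n:], trace, n_iter, converged


def jcnmf_fit(X1: ExpressionMatrix, X2: ExpressionMatrix, k: int,
              lambda_: float = 1.0, mode: str = "soft",
              max_iter: int = 5000, tol: float = 1e-6, seed: int = 0,
              n_restarts: int = 5,
              R: ConservedCorrelation | None = None) -> FactorizationResult:
    """Fit the paired factorization; deterministic given ``seed``.

    Parameters
    ----------
    k : int
        Number of modules; must satisfy ``k <= min(n_tissues, n_genes)``.
    lambda_ : float
        Weight of the Gram-matrix penalty (``soft`` mode only).
    mode : {"soft", "hard", "none"}
        Soft Gram constraint, shared-W joint NMF, or independent NMFs.
    n_restarts : int
        Random restarts; the run with the lowest final objective wins.
    R : ConservedCorrelation, optional
        Precomputed correlation target; estimated from the data when omitted.
    """
    if mode not in ("soft", "hard", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    if X1.tissue_ids != X2.tissue_ids or X1.gene_ids != X2.gene_ids:
        raise AlignmentError("X1 and X2 must share tissue and gene orderings")
    m, n = X1.values.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"k={k} outside [1, min(m={m}, n={n})]")
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    A1, A2 = X1.values, X2.values
    if not A1.any() or not A2.any():
        raise ValueError("degenerate input: an expression matrix is all zero")

    lam = float(lambda_) if mode == "soft" else 0.0
    Rmat: np.ndarray | None = None
    if mode == "soft":
        if R is None:
            R = estimate_conserved_correlation(X1, X2)
        Rmat = R.R

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for child in children:
        rng = np.random.default_rng(child)
        if mode == "hard":
            W, H1, H2, trace, n_iter, conv = _fit_hard(
                A1, A2, k, rng, max_iter, tol)
            run = (W, H1, W, H2, trace, n_iter, conv)
        else:
            W1, H1, W2, H2, trace, n_iter, conv = _fit_pair(
                A1, A2, k, lam, Rmat, rng, max_iter, tol)
            run = (W1, H1, W2, H2, trace, n_iter, conv)
        if best is None or run[4][-1] < best[4][-1]:
            best = run
    W1, H1, W2, H2, trace, n_iter, conv = best
    residual = float(np.linalg.norm(W1 @ W1.T - W2 @ W2.T))
    return FactorizationResult(
        W1=W1, W2=W2, H1=H1, H2=H2, k=k, mode=mode, lambda_=float(lambda_),
        objective_trace=[float(v) for v in trace],
        constraint_residual=residual, seed=seed, n_iter=n_iter,
        converged=conv, R=Rmat,
        tissue_ids=list(X1.tissue_ids), gene_ids=list(X1.gene_ids),
    )
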