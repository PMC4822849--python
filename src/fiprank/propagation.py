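"""Degree-normalized score propagation with restart, and gene ranking.

Scores solve the random-walk-with-restart fixed point

    Q = (1 - d) * (I - d * W D^{-1})^{-1} * e

where D is the diagonal of row sums of the symmetric weight matrix W (so
M = W D^{-1} is column-stochastic on non-isolated nodes), e is the
expression-derived restart prior and d < 1 balances network diffusion
against restart. Because columns of M sum to one, a prior summing to one
yields scores summing to one on connected networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core_io import RankingResult, SeedSet
from .similarity import WeightMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    """d: network weight (restart probability is 1-d); d = 0.9 by default.

    d must be strictly below 1 (d = 1 makes the linear system singular).
    The direct sparse solve is the default; the fixed-point iteration is kept
    as an independent cross-check and agrees to ~1e-8.
    """

    d: float = 0.9
    solver: str = "direct"
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"d={self.d} must lie in [0, 1)")
        if self.solver not in ("direct", "iterative"):
            raise ValueError("solver must be 'direct' or 'iterative'")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


def build_transition(W: WeightMatrix) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Column-normalize W into M = W D^{-1}; returns (M, isolated mask).

    Columns of M belonging to nodes with positive degree sum to one; columns
    of isolated nodes (zero degree) are left zero, so those nodes keep only
    their restart mass (1-d)*e_i after propagation.
    """
    mat = W.matrix.tocsr()
    if (mat.data < 0).any():
        raise ValueError("negative weights in W")
    deg = np.asarray(mat.sum(axis=0)).ravel()
    isolated = deg == 0
    if isolated.any():
        log.info("%d isolated node(s) receive restart mass only", int(isolated.sum()))
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg))
    M = (mat @ sparse.diags(inv)).tocsr()
    return M, isolated


def propagate(
    M: sparse.spmatrix, e: np.ndarray, cfg: PropagationConfig = PropagationConfig()
) -> np.ndarray:
    """Solve Q = (1-d)(I - d M)^{-1} e.

    solver='direct' uses a sparse LU solve; solver='iterative' runs the
    power iteration q <- d*M*q + (1-d)*e from q0 = e until the max-abs
    update falls below tol, erroring with the residual if max_iter is hit.
    """
    e = np.asarray(e, dtype=float)
    if (e < 0).any():
        raise ValueError("prior must be nonnegative")
    n = e.size
    if M.shape != (n, n):
        raise ValueError("transition matrix and prior dimensions disagree")
    d = cfg.d
    if d == 0.0:
        return e.copy()
    if cfg.solver == "direct":
        A = (sparse.identity(n, format="csc") - d * M.tocsc()).tocsc()
        return spsolve(A, (1.0 - d) * e)
    q = e.copy()
    restart = (1.0 - d) * e
    for _ in range(cfg.max_iter):
        q_next = d * (M @ q) + restart
        delta = np.abs(q_next - q).max()
        q = q_next
        if delta < cfg.tol:
            return q
    raise RuntimeError(
        f"propagation failed to converge in {cfg.max_iter} iterations "
        f"(last update {delta:.3e} > tol {cfg.tol:.1e})"
    )


def rank_genes(
    q: pd.Series,
    seeds: SeedSet,
    candidates: frozenset[str] | None = None,
    include_seeds: bool = True,
) -> RankingResult:
    """Sort genes by descending relevance score into a 1-based ranking.

    Ties share the average rank; listing order is deterministic (score, then
    gene name). With include_seeds=False only candidate genes are ranked —
    the view used when reporting novel predictions.
    """
    if candidates is not None:
        keep = set(candidates) | (set(seeds.genes) if include_seeds else set())
        q = q.loc[[g for g in q.index if g in keep]]
    elif not include_seeds:
        q = q.loc[[g for g in q.index if g not in seeds.genes]]
    return RankingResult.from_scores(q, seeds.genes)
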