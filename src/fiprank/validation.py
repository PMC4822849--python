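"""Evaluation harness: LOOCV, k-fold CV, rank-based ROC/AUC, top-k seed
counts, the alpha/beta/gamma/d grid search, and the two channel ablations.

Cross-validation exploits a structural fact of the scoring model: the
propagated score Q depends only on the expression prior and the fused weight
matrix, never on which genes carry the seed label. Removing a seed therefore
does not change any score — it only moves the gene from the positive set to
the ranked pool — so one propagation serves every held-out round, and the
LOOCV AUC equals the Mann-Whitney statistic of seed scores against candidate
scores: AUC = 1 - mean((r - 1) / (n - 1)) over test-gene ranks r among the
n = |candidates| + 1 genes each round ranks. Seeds still held in are never
counted as negatives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationMap,
    CooccurrenceTable,
    ExpressionMatrix,
    InteractionNetwork,
    RankingResult,
    SeedSet,
)
from .pipeline import ScoredUniverse, score_from_channels, score_genes
from .propagation import PropagationConfig, rank_genes
from .similarity import FusionParams

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-test-gene ranks, a pooled ROC curve, and the rank-based AUC."""

    records: pd.DataFrame  # columns: gene, rank, n
    roc: np.ndarray  # (k, 2) array of (FPR, TPR) points
    auc: float


@dataclass(frozen=True)
class GridPoint:
    alpha: float
    beta: float
    gamma: float
    d: float
    top50_seeds: int
    top100_seeds: int
    loocv_auc: float  # NaN when AUC was not requested


# ---------------------------------------------------------------------------
# Rank -> ROC machinery
# ---------------------------------------------------------------------------


def _rank_among(q: pd.Series, gene: str, negatives: np.ndarray) -> tuple[float, int]:
    """Average-tie rank of ``gene`` among negatives ∪ {gene}, and pool size."""
    qs = q.loc[gene]
    r = 1.0 + float((negatives > qs).sum()) + 0.5 * float((negatives == qs).sum())
    return r, negatives.size + 1


def _cv_result(ranks: np.ndarray, ns: np.ndarray, genes: list[str]) -> CVResult:
    u = (ranks - 1.0) / np.maximum(ns - 1.0, 1.0)
    auc = float(1.0 - u.mean())
    xs = np.sort(u)
    tpr = np.arange(1, xs.size + 1) / xs.size
    roc = np.vstack(
        [[0.0, 0.0], np.column_stack([xs, tpr]), [1.0, 1.0]]
    )
    records = pd.DataFrame({"gene": genes, "rank": ranks, "n": ns})
    return CVResult(records=records, roc=roc, auc=auc)


def cv_from_scores(q: pd.Series, seeds: SeedSet, candidates: frozenset[str]) -> CVResult:
    """LOOCV over precomputed scores: rank each seed among candidates ∪ itself."""
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed genes for cross-validation")
    cand = sorted(candidates)
    neg = q.loc[cand].to_numpy()
    genes = sorted(seeds.genes)
    ranks, ns = [], []
    for s in genes:
        r, n = _rank_among(q, s, neg)
        ranks.append(r)
        ns.append(n)
    return _cv_result(np.array(ranks), np.array(ns, dtype=float), genes)


def loocv(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
) -> CVResult:
    """Leave-one-out CV: each seed is held out in turn and its recovered rank
    among the candidate pool is recorded; ranks pool into a ROC/AUC."""
    scored = score_genes(net, expr, ann, cooc, seeds, params, cfg)
    return cv_from_scores(scored.q, scored.seeds, scored.candidates)


def kfold_cv(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    k: int,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
    rng_seed: int = 42,
) -> CVResult:
    """k-fold CV over the seed set (seeded shuffle into folds).

    Each fold is held out and its members ranked exactly as in LOOCV; fold
    mates are excluded from each other's negative pool, so with k equal to
    the seed count this reduces to LOOCV.
    """
    scored = score_genes(net, expr, ann, cooc, seeds, params, cfg)
    seed_list = sorted(scored.seeds.genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(seed_list):
        raise ValueError(f"k={k} exceeds seed count {len(seed_list)}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(seed_list))
    folds = [sorted(seed_list[i] for i in order[f::k]) for f in range(k)]

    neg = scored.q.loc[sorted(scored.candidates)].to_numpy()
    genes, ranks, ns = [], [], []
    for fold in folds:
        for s in fold:
            r, n = _rank_among(scored.q, s, neg)
            genes.append(s)
            ranks.append(r)
            ns.append(n)
    return _cv_result(np.array(ranks), np.array(ns, dtype=float), genes)


def topk_seed_count(ranking: RankingResult, k: int) -> int:
    """Number of seed genes among the top k entries of a ranking."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    if k <= 0:
        return 0
    return int(ranking.entries.head(k)["is_seed"].sum())


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


DEFAULT_COEF_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
DEFAULT_D_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


def _evaluate_point(
    scored_inputs,
    params: FusionParams,
    cfg: PropagationConfig,
    compute_auc: bool,
) -> GridPoint:
    channels, prior, seeds, candidates = scored_inputs
    q = score_from_channels(channels, prior, params, cfg)
    ranking = rank_genes(q, seeds, candidates, include_seeds=True)
    n = len(ranking)
    top50 = topk_seed_count(ranking, min(50, n))
    top100 = topk_seed_count(ranking, min(100, n))
    auc = float("nan")
    if compute_auc and len(seeds) >= 2:
        auc = cv_from_scores(q, seeds, candidates).auc
    return GridPoint(params.alpha, params.beta, params.gamma, cfg.d, top50, top100, auc)


def _better(a: GridPoint, b: GridPoint) -> bool:
    """True when a beats b: AUC first (when finite), then top-50, top-100."""
    ka = (
        a.loocv_auc if np.isfinite(a.loocv_auc) else -1.0,
        a.top50_seeds,
        a.top100_seeds,
        -a.alpha, -a.beta, -a.gamma, -a.d,
    )
    kb = (
        b.loocv_auc if np.isfinite(b.loocv_auc) else -1.0,
        b.top50_seeds,
        b.top100_seeds,
        -b.alpha, -b.beta, -b.gamma, -b.d,
    )
    return ka > kb


def grid_search(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    alphas=DEFAULT_COEF_GRID,
    betas=DEFAULT_COEF_GRID,
    gammas=DEFAULT_COEF_GRID,
    d_values=DEFAULT_D_GRID,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
    mode: str = "two_stage",
    compute_auc: bool = True,
) -> tuple[list[GridPoint], GridPoint]:
    """Sweep fusion coefficients and the diffusion parameter d.

    mode='two_stage' mirrors the published procedure: the coefficient grid is
    swept at the default d, the best combination kept, then d swept for that
    combination. mode='joint' evaluates the full product. The degenerate
    all-zero coefficient point is skipped. Returns (all points, best point).
    """
    alphas, betas, gammas = list(alphas), list(betas), list(gammas)
    d_values = list(d_values)
    if not (alphas and betas and gammas and d_values):
        raise ValueError("empty grid")
    if mode not in ("two_stage", "joint"):
        raise ValueError("mode must be 'two_stage' or 'joint'")

    scored = score_genes(net, expr, ann, cooc, seeds, params, cfg)
    inputs = (scored.channels, scored.prior, scored.seeds, scored.candidates)

    combos = [
        c for c in itertools.product(alphas, betas, gammas) if any(v > 0 for v in c)
    ]
    if not combos:
        raise ValueError("grid contains only the degenerate all-zero point")

    points: list[GridPoint] = []
    best: GridPoint | None = None

    def consider(pt: GridPoint) -> None:
        nonlocal best
        points.append(pt)
        if best is None or _better(pt, best):
            best = pt

    if mode == "joint":
        for a, b, g in combos:
            p = replace(params, alpha=a, beta=b, gamma=g)
            for d in d_values:
                consider(_evaluate_point(inputs, p, replace(cfg, d=d), compute_auc))
    else:
        stage1_best: GridPoint | None = None
        for a, b, g in combos:
            p = replace(params, alpha=a, beta=b, gamma=g)
            pt = _evaluate_point(inputs, p, cfg, compute_auc)
            consider(pt)
            if stage1_best is None or _better(pt, stage1_best):
                stage1_best = pt
        p = replace(
            params, alpha=stage1_best.alpha, beta=stage1_best.beta, gamma=stage1_best.gamma
        )
        for d in d_values:
            if d == cfg.d:
                continue  # already evaluated in stage 1
            consider(_evaluate_point(inputs, p, replace(cfg, d=d), compute_auc))

    return points, best


def grid_to_frame(points: list[GridPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


# ---------------------------------------------------------------------------
# Ablations
# ---------------------------------------------------------------------------


def ablation_shuffle_pearson(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
    mode: str = "without_replacement",
    reps: int = 100,
    rng_seed: int = 42,
    identity: bool = False,
) -> pd.DataFrame:
    """Destroy the edge-specific co-expression signal and re-rank.

    Per repetition the per-edge Pearson values are reassigned from the pool
    of observed values — a permutation ('without_replacement') or a bootstrap
    resample ('with_replacement') — W is re-fused and the top-50/top-100
    seed counts recorded. ``identity=True`` forces the identity permutation
    (a self-check: counts must equal the unablated run).
    """
    if mode not in ("with_replacement", "without_replacement"):
        raise ValueError("mode must be 'with_replacement' or 'without_replacement'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scored = score_genes(net, expr, ann, cooc, seeds, params, cfg)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for rep in range(reps):
        ch = scored.channels.copy()
        if identity:
            pass
        elif mode == "without_replacement":
            ch.P = rng.permutation(ch.P)
        else:
            ch.P = rng.choice(ch.P, size=ch.P.size, replace=True)
        q = score_from_channels(ch, scored.prior, params, cfg)
        ranking = rank_genes(q, scored.seeds, scored.candidates, include_seeds=True)
        n = len(ranking)
        rows.append(
            {
                "rep": rep,
                "top50_seeds": topk_seed_count(ranking, min(50, n)),
                "top100_seeds": topk_seed_count(ranking, min(100, n)),
            }
        )
    return pd.DataFrame(rows)


def ablation_unit_credibility(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
) -> CVResult:
    """Set the credibility channel to 1 on every edge and re-run LOOCV.

    Removes interaction-reliability information while keeping topology,
    co-expression and function; compares against the unablated LOOCV AUC.
    """
    scored = score_genes(net, expr, ann, cooc, seeds, params, cfg)
    ch = scored.channels.copy()
    ch.S = np.ones_like(ch.S)
    q = score_from_channels(ch, scored.prior, params, cfg)
    return cv_from_scores(q, scored.seeds, scored.candidates)
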