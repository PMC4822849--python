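"""Edge similarity channels and their fusion into the weight matrix W.

Three per-edge channels are combined linearly:

* S(i,j) — interaction credibility, derived from weighted literature
  co-occurrence counts (documents / paragraphs / sentences), or taken from a
  precomputed edge confidence when the network ships one;
* P(i,j) — Pearson co-expression over the pooled control+disease samples;
* F(i,j) — shared functional significance: the sum over GO terms annotated
  to both genes of 1/|genes annotated to the term|.

W = alpha*S' + beta*P' + gamma*F' on network edges (zero elsewhere), where the
primes denote the configured Pearson sign transform and optional per-channel
min-max rescaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .core_io import (
    AnnotationMap,
    CooccurrenceTable,
    ExpressionMatrix,
    InteractionNetwork,
    canonical_pair,
)

log = logging.getLogger(__name__)

PEARSON_TRANSFORMS = ("raw", "abs", "clip0")
COMPONENT_NORMS = ("none", "minmax")


@dataclass(frozen=True)
class FusionParams:
    """Coefficients and switches for the edge-weight fusion.

    alpha, beta, gamma weight the credibility, co-expression and functional
    channels and live in [0, 1]; the optimum reported for the thrombosis
    study is (0.8, 0.5, 0.9), used as the default. t is the credibility
    exponent (0.6); v_d, v_p, v_s weight document / paragraph / sentence
    co-occurrences (1, 2, 0.2).
    """

    alpha: float = 0.8
    beta: float = 0.5
    gamma: float = 0.9
    t: float = 0.6
    v_d: float = 1.0
    v_p: float = 2.0
    v_s: float = 0.2
    component_norm: str = "minmax"
    pearson_transform: str = "abs"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "t"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("v_d", "v_p", "v_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.pearson_transform not in PEARSON_TRANSFORMS:
            raise ValueError(f"pearson_transform must be one of {PEARSON_TRANSFORMS}")
        if self.component_norm not in COMPONENT_NORMS:
            raise ValueError(f"component_norm must be one of {COMPONENT_NORMS}")


@dataclass
class EdgeChannels:
    """Per-edge channel values S', P', F' after transform and normalization.

    ``edges`` is a list of canonical gene pairs; the arrays are aligned to it.
    Ablations operate on this object: replacing S with ones or permuting P and
    re-fusing reproduces the channel-knockout experiments.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    S: np.ndarray
    P: np.ndarray
    F: np.ndarray

    def copy(self) -> "EdgeChannels":
        return EdgeChannels(
            nodes=list(self.nodes),
            edges=list(self.edges),
            S=self.S.copy(),
            P=self.P.copy(),
            F=self.F.copy(),
        )


@dataclass
class WeightMatrix:
    """Sparse symmetric nonnegative weight matrix over an ordered node list."""

    nodes: list[str]
    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.matrix.shape != (n, n):
            raise ValueError("weight matrix shape does not match node list")

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}


# ---------------------------------------------------------------------------
# S channel: literature co-occurrence -> interaction credibility
# ---------------------------------------------------------------------------


def cooccurrence_count(
    counts: tuple[int, int, int], params: FusionParams = FusionParams()
) -> float:
    """Weighted co-occurrence score C_ij = v_d*n_doc + v_p*n_para + v_s*n_sent."""
    nd, npar, ns = counts
    if min(nd, npar, ns) < 0:
        raise ValueError("negative co-occurrence count")
    return params.v_d * nd + params.v_p * npar + params.v_s * ns


def interaction_credibility(
    c_ij: float, c_i: float, c_j: float, c_all: float, t: float = 0.6
) -> float:
    """Credibility S = C_ij^t * (C_ij * C_.. / (C_i. * C_.j))^(1-t).

    The first factor rewards absolute evidence volume, the second the
    specificity of the pair relative to each gene's total mention rate.
    S = 0 whenever C_ij = 0; at t = 1 S reduces to C_ij.
    """
    if c_ij < 0:
        raise ValueError("C_ij must be nonnegative")
    if c_ij == 0:
        return 0.0
    if min(c_i, c_j, c_all) <= 0:
        raise ValueError("positive C_ij with zero marginal: inconsistent table")
    return c_ij**t * (c_ij * c_all / (c_i * c_j)) ** (1.0 - t)


def credibility_scores(
    cooc: CooccurrenceTable, params: FusionParams = FusionParams()
) -> dict[tuple[str, str], float]:
    """Per-pair credibility over the whole table (marginals recomputed)."""
    c_pair = {
        pair: cooccurrence_count(counts, params)
        for pair, counts in cooc.pair_counts.items()
    }
    c_gene: dict[str, float] = {}
    for (a, b), c in c_pair.items():
        c_gene[a] = c_gene.get(a, 0.0) + c
        c_gene[b] = c_gene.get(b, 0.0) + c
    c_all = sum(c_pair.values())
    return {
        pair: interaction_credibility(c, c_gene[pair[0]], c_gene[pair[1]], c_all, params.t)
        if c > 0
        else 0.0
        for pair, c in c_pair.items()
    }


# ---------------------------------------------------------------------------
# P channel: pooled-sample Pearson co-expression
# ---------------------------------------------------------------------------


def pearson_coexpression(expr: ExpressionMatrix, i: str, j: str) -> float:
    """Sample Pearson correlation of two gene rows over all pooled samples.

    Uses the (h-1)-denominator form: mean-center each row, divide by the
    sample SD, average the products. Zero-variance rows (flat genes) give an
    undefined correlation; 0 is returned with a warning.
    """
    xi, xj = expr.row(i), expr.row(j)
    return _pearson_rows(xi, xj, label=f"({i}, {j})")


def _pearson_rows(xi: np.ndarray, xj: np.ndarray, label: str = "") -> float:
    h = xi.size
    if h < 3:
        raise ValueError("need at least 3 pooled samples for Pearson")
    si, sj = xi.std(ddof=1), xj.std(ddof=1)
    if si == 0.0 or sj == 0.0:
        log.warning("zero-variance gene in pair %s; Pearson set to 0", label)
        return 0.0
    zi = (xi - xi.mean()) / si
    zj = (xj - xj.mean()) / sj
    return float(np.dot(zi, zj) / (h - 1))


# ---------------------------------------------------------------------------
# F channel: shared GO-term significance
# ---------------------------------------------------------------------------


def term_significance(term: str, ann: AnnotationMap) -> float:
    """sig(f_m) = 1 / |Gene(f_m)|; rarer terms carry more weight."""
    return 1.0 / ann.term_size(term)


def functional_similarity(i: str, j: str, ann: AnnotationMap) -> float:
    """Sum of term significances over the GO terms shared by both genes."""
    shared = ann.terms_of(i) & ann.terms_of(j)
    return sum(term_significance(t, ann) for t in shared)


# ---------------------------------------------------------------------------
# Expression prior
# ---------------------------------------------------------------------------


def expression_prior(expr: ExpressionMatrix, normalize: bool = True) -> pd.Series:
    """Restart prior e_i = |sum over controls - sum over disease samples|.

    Genes whose total expression differs most between groups restart the walk
    most often. By default the vector is rescaled to sum to 1 (rankings are
    invariant to positive rescaling because propagation is linear in e); when
    every entry is zero the raw zero vector is returned.
    """
    ctrl = expr.values[:, expr.control_mask].sum(axis=1)
    dis = expr.values[:, expr.disease_mask].sum(axis=1)
    e = np.abs(ctrl - dis)
    if normalize:
        total = e.sum()
        if total > 0:
            e = e / total
    return pd.Series(e, index=expr.genes, name="e")


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(initial=0.0), x.max(initial=0.0)
    if x.size == 0 or hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def compute_edge_channels(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None = None,
    params: FusionParams = FusionParams(),
) -> EdgeChannels:
    """Evaluate S', P', F' on every network edge.

    The S channel comes from the co-occurrence table when given; otherwise
    from the network's precomputed edge confidences rescaled to [0, 1];
    otherwise it is all zero (with a warning). P is computed vectorized over
    standardized expression rows; zero-variance rows yield 0.
    """
    nodes = sorted(net.nodes)
    edges = sorted(net.edges)
    m = len(edges)

    # S channel
    S = np.zeros(m)
    if cooc is not None:
        scores = credibility_scores(cooc, params)
        for k, pair in enumerate(edges):
            S[k] = scores.get(pair, 0.0)
    elif net.has_confidence:
        conf = np.array([net.edges[p] for p in edges], dtype=float)
        top = conf.max(initial=0.0)
        S = conf / top if top > 0 else conf
    elif m:
        log.warning("no co-occurrence table or edge confidences; S channel is zero")

    # P channel, vectorized: correlation = dot of standardized rows / (h-1)
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    X = expr.values
    sd = X.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.warning("%d zero-variance gene(s); their Pearson values set to 0", int(flat.sum()))
    safe_sd = np.where(flat, 1.0, sd)
    Z = (X - X.mean(axis=1, keepdims=True)) / safe_sd[:, None]
    Z[flat] = 0.0
    ia = np.array([gene_idx[a] for a, _ in edges], dtype=int)
    ib = np.array([gene_idx[b] for _, b in edges], dtype=int)
    P = (
        np.einsum("ij,ij->i", Z[ia], Z[ib]) / (expr.h - 1)
        if m
        else np.zeros(0)
    )

    # F channel
    F = np.array([functional_similarity(a, b, ann) for a, b in edges])

    if params.pearson_transform == "abs":
        P = np.abs(P)
    elif params.pearson_transform == "clip0":
        P = np.clip(P, 0.0, None)

    if params.component_norm == "minmax":
        S, P, F = _minmax(S), _minmax(P), _minmax(F)

    return EdgeChannels(nodes=nodes, edges=edges, S=S, P=P, F=F)


def fuse_channels(channels: EdgeChannels, params: FusionParams) -> WeightMatrix:
    """W = alpha*S' + beta*P' + gamma*F' on edges, symmetric, zero off-edge."""
    if params.alpha == params.beta == params.gamma == 0.0:
        raise ValueError("degenerate fusion: alpha = beta = gamma = 0")
    w = params.alpha * channels.S + params.beta * channels.P + params.gamma * channels.F
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite fused weight")
    idx = {g: i for i, g in enumerate(channels.nodes)}
    n = len(channels.nodes)
    ia = np.array([idx[a] for a, _ in channels.edges], dtype=int)
    ib = np.array([idx[b] for _, b in channels.edges], dtype=int)
    mat = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([ia, ib]), np.concatenate([ib, ia]))),
        shape=(n, n),
    ).tocsr()
    return WeightMatrix(nodes=channels.nodes, matrix=mat)


def build_weight_matrix(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None = None,
    params: FusionParams = FusionParams(),
) -> WeightMatrix:
    """Convenience composition: compute channels on edges, then fuse."""
    return fuse_channels(compute_edge_channels(net, expr, ann, cooc, params), params)
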