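"""End-to-end composition: harmonize -> channels -> W -> propagate -> rank."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import (
    AnnotationMap,
    CooccurrenceTable,
    ExpressionMatrix,
    Harmonized,
    InteractionNetwork,
    RankingResult,
    SeedSet,
    harmonize_universe,
)
from .propagation import PropagationConfig, build_transition, propagate, rank_genes
from .similarity import (
    EdgeChannels,
    FusionParams,
    compute_edge_channels,
    expression_prior,
    fuse_channels,
)


@dataclass
class ScoredUniverse:
    """Everything the validation harness needs from one scoring pass."""

    harmonized: Harmonized
    channels: EdgeChannels
    prior: pd.Series
    q: pd.Series

    @property
    def seeds(self) -> SeedSet:
        return self.harmonized.seeds

    @property
    def candidates(self) -> frozenset[str]:
        return self.harmonized.candidates


def score_from_channels(
    channels: EdgeChannels,
    prior: pd.Series,
    params: FusionParams,
    cfg: PropagationConfig,
) -> pd.Series:
    """Fuse precomputed channels and propagate the prior over them."""
    W = fuse_channels(channels, params)
    M, _ = build_transition(W)
    e = prior.reindex(W.nodes).fillna(0.0).to_numpy()
    q = propagate(M, e, cfg)
    return pd.Series(q, index=W.nodes, name="q")


def score_genes(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    cooc: CooccurrenceTable | None,
    seeds: SeedSet,
    params: FusionParams = FusionParams(),
    cfg: PropagationConfig = PropagationConfig(),
) -> ScoredUniverse:
    """Run the full scoring pipeline on raw inputs."""
    har = harmonize_universe(net, expr, seeds)
    channels = compute_edge_channels(har.network, har.expression, ann, cooc, params)
    prior = expression_prior(har.expression)
    q = score_from_channels(channels, prior, params, cfg)
    return ScoredUniverse(harmonized=har, channels=channels, prior=prior, q=q)


def rank_candidates(scored: ScoredUniverse, include_seeds: bool = True) -> RankingResult:
    return rank_genes(scored.q, scored.seeds, scored.candidates, include_seeds)
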