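"""Similarity channels: credibility, co-expression, function, fusion, prior."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fiprank import (
    AnnotationMap,
    ExpressionMatrix,
    FusionParams,
    build_weight_matrix,
    compute_edge_channels,
    cooccurrence_count,
    credibility_scores,
    expression_prior,
    functional_similarity,
    fuse_channels,
    interaction_credibility,
    pearson_coexpression,
    term_significance,
)
from fiprank.core_io import CooccurrenceTable, InteractionNetwork
from fiprank.similarity import EdgeChannels, _pearson_rows


class TestCooccurrenceCount:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1, 0), 3.0), ((0, 0, 0), 0.0), ((2, 1, 1), 4.2)],
    )
    def test_weighted_sum_with_default_weights(self, counts, expected):
        assert cooccurrence_count(counts) == pytest.approx(expected)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            cooccurrence_count((-1, 0, 0))


class TestInteractionCredibility:
    def test_zero_evidence_gives_zero(self):
        assert interaction_credibility(0.0, 10.0, 8.0, 100.0, t=0.6) == 0.0

    def test_t_one_reduces_to_count(self):
        assert interaction_credibility(4.0, 10.0, 8.0, 100.0, t=1.0) == pytest.approx(4.0)

    def test_t_zero_reduces_to_specificity_ratio(self):
        expected = 4.0 * 100.0 / (10.0 * 8.0)
        assert interaction_credibility(4.0, 10.0, 8.0, 100.0, t=0.0) == pytest.approx(expected)

    def test_worked_value(self):
        # 4^0.6 * (4*100/(10*8))^0.4 = 4^0.6 * 5^0.4, evaluated independently
        expected = math.exp(0.6 * math.log(4) + 0.4 * math.log(5))
        assert interaction_credibility(4.0, 10.0, 8.0, 100.0, t=0.6) == pytest.approx(
            expected, rel=1e-12
        )

    def test_symmetric_in_gene_order(self):
        a = interaction_credibility(4.0, 10.0, 8.0, 100.0, t=0.6)
        b = interaction_credibility(4.0, 8.0, 10.0, 100.0, t=0.6)
        assert a == pytest.approx(b, rel=1e-15)

    def test_inconsistent_marginals_error(self):
        with pytest.raises(ValueError, match="marginal"):
            interaction_credibility(4.0, 0.0, 8.0, 100.0, t=0.6)

    def test_table_marginals_recomputed(self, tiny_cooc):
        params = FusionParams()
        scores = credibility_scores(tiny_cooc, params)
        # hand-computed pair scores: AB=4+4+0.2=8.2, BC=2+2=4, AC=1+2+0.2=3.2
        c = {("A", "B"): 8.2, ("B", "C"): 4.0, ("A", "C"): 3.2}
        tot = sum(c.values())
        marg = {"A": 8.2 + 3.2, "B": 8.2 + 4.0, "C": 4.0 + 3.2}
        for pair, cij in c.items():
            expected = interaction_credibility(
                cij, marg[pair[0]], marg[pair[1]], tot, 0.6
            )
            assert scores[pair] == pytest.approx(expected, rel=1e-12)


class TestPearson:
    def _expr(self, rows: dict) -> ExpressionMatrix:
        genes = list(rows)
        values = np.array([rows[g] for g in genes], dtype=float)
        h = values.shape[1]
        return ExpressionMatrix(
            genes=genes,
            samples=[f"s{i}" for i in range(h)],
            values=values,
            group=np.array(
                ["control"] * (h // 2) + ["disease"] * (h - h // 2), dtype=object
            ),
        )

    def test_identical_rows(self):
        expr = self._expr({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        assert pearson_coexpression(expr, "A", "B") == pytest.approx(1.0)

    def test_exact_negation(self):
        expr = self._expr({"A": [1, 2, 3, 4], "B": [-1, -2, -3, -4]})
        assert pearson_coexpression(expr, "A", "B") == pytest.approx(-1.0)

    def test_perfect_linear_relation(self):
        expr = self._expr({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8]})
        assert pearson_coexpression(expr, "A", "B") == pytest.approx(1.0)

    def test_zero_variance_returns_zero_with_warning(self, caplog):
        expr = self._expr({"A": [1, 2, 3, 4], "B": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            assert pearson_coexpression(expr, "A", "B") == 0.0
        assert "zero-variance" in caplog.text

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            h = int(rng.integers(3, 30))
            x, y = rng.normal(size=(2, h))
            # independent two-pass oracle: means, then SDs, then products
            mx, my = x.mean(), y.mean()
            sx = math.sqrt(((x - mx) ** 2).sum() / (h - 1))
            sy = math.sqrt(((y - my) ** 2).sum() / (h - 1))
            expected = sum((x - mx) / sx * (y - my) / sy) / (h - 1)
            assert _pearson_rows(x, y) == pytest.approx(expected, abs=1e-12)


class TestFunctionalSimilarity:
    def test_term_significance(self, tiny_ann):
        assert term_significance("GO:1", tiny_ann) == pytest.approx(0.5)
        assert term_significance("GO:3", tiny_ann) == pytest.approx(1.0)
        with pytest.raises(KeyError):
            term_significance("GO:999", tiny_ann)

    def test_shared_term_sum(self, tiny_ann):
        # A and B share GO:1 (|2|) and GO:2 (|4|): 0.5 + 0.25
        assert functional_similarity("A", "B", tiny_ann) == pytest.approx(0.75)

    def test_no_shared_terms(self, tiny_ann):
        assert functional_similarity("D", "Z", tiny_ann) == 0.0

    def test_self_similarity_is_own_term_sum(self):
        ann = AnnotationMap.from_pairs(
            [("A", "T1"), ("B", "T1"), ("A", "T2")]
            + [(f"X{i}", "T2") for i in range(4)]
        )
        # A's terms: T1 (size 2) and T2 (size 5)
        assert functional_similarity("A", "A", ann) == pytest.approx(0.5 + 0.2)

    def test_matches_brute_force_term_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_terms = int(rng.integers(1, 50))
            genes = [f"g{i}" for i in range(int(rng.integers(2, 20)))]
            pairs = [
                (g, f"T{t}")
                for g in genes
                for t in range(n_terms)
                if rng.random() < 0.3
            ]
            if not pairs:
                continue
            ann = AnnotationMap.from_pairs(pairs)
            i, j = rng.choice(genes, 2).tolist()
            gi, gj = i.upper(), j.upper()
            brute = sum(
                1.0 / len(members)
                for term, members in ann.term_to_genes.items()
                if gi in members and gj in members
            )
            assert functional_similarity(gi, gj, ann) == pytest.approx(brute, abs=1e-12)


class TestExpressionPrior:
    def _expr(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            genes=[f"g{i}".upper() for i in range(values.shape[0])],
            samples=["s1", "s2", "s3", "s4"],
            values=values,
            group=np.array(["control", "control", "disease", "disease"], dtype=object),
        )

    def test_balanced_gene_gets_zero(self):
        expr = self._expr([[1, 2, 3, 0], [1, 1, 1, 1]])
        e = expression_prior(expr, normalize=False)
        assert e["G0"] == pytest.approx(0.0)

    def test_single_informative_gene_takes_all_mass(self):
        expr = self._expr([[5, 0, 0, 0], [1, 1, 1, 1]])
        e = expression_prior(expr)
        assert e["G0"] == pytest.approx(1.0)
        assert e["G1"] == pytest.approx(0.0)

    def test_normalization_proportions(self):
        expr = self._expr([[3, 0, 0, 0], [1, 0, 0, 0]])
        e = expression_prior(expr)
        assert e.to_numpy() == pytest.approx([0.75, 0.25])


class TestFusion:
    def _channels(self, S, P, F):
        nodes = ["A", "B", "C"]
        edges = [("A", "B"), ("B", "C")]
        return EdgeChannels(
            nodes=nodes, edges=edges, S=np.array(S), P=np.array(P), F=np.array(F)
        )

    def test_projection_onto_s_channel(self):
        ch = self._channels([0.3, 0.7], [0.9, 0.1], [0.5, 0.5])
        W = fuse_channels(ch, FusionParams(alpha=1.0, beta=0.0, gamma=0.0, component_norm="none"))
        assert W.matrix[0, 1] == pytest.approx(0.3)
        assert W.matrix[1, 2] == pytest.approx(0.7)

    def test_hand_fused_weight_at_reported_optimum(self):
        ch = self._channels([0.5, 0.0], [0.2, 0.0], [0.1, 0.0])
        W = fuse_channels(ch, FusionParams(alpha=0.8, beta=0.5, gamma=0.9, component_norm="none"))
        assert W.matrix[0, 1] == pytest.approx(0.8 * 0.5 + 0.5 * 0.2 + 0.9 * 0.1)

    def test_non_edges_stay_zero(self):
        ch = self._channels([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        W = fuse_channels(ch, FusionParams())
        assert W.matrix[0, 2] == 0.0  # (A, C) is not an edge

    def test_degenerate_fusion_errors(self):
        ch = self._channels([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            fuse_channels(ch, FusionParams(alpha=0.0, beta=0.0, gamma=0.0))

    def test_symmetry_and_support(self, tiny_net, tiny_expr, tiny_ann, tiny_cooc):
        W = build_weight_matrix(tiny_net, tiny_expr, tiny_ann, tiny_cooc)
        dense = W.matrix.toarray()
        np.testing.assert_allclose(dense, dense.T)
        assert (dense >= 0).all()
        idx = W.index
        for i in range(len(W.nodes)):
            for j in range(len(W.nodes)):
                if dense[i, j] != 0:
                    a, b = W.nodes[i], W.nodes[j]
                    assert (min(a, b), max(a, b)) in tiny_net.edges

    @pytest.mark.parametrize("transform", ["abs", "clip0"])
    def test_nonnegative_weights_under_sign_transforms(
        self, tiny_net, tiny_expr, tiny_ann, tiny_cooc, transform
    ):
        params = FusionParams(pearson_transform=transform, component_norm="none")
        W = build_weight_matrix(tiny_net, tiny_expr, tiny_ann, tiny_cooc, params)
        assert (W.matrix.data >= 0).all()

    def test_precomputed_confidence_used_as_credibility(self, tiny_expr, tiny_ann):
        net = InteractionNetwork(
            nodes=frozenset({"A", "B", "C"}),
            edges={("A", "B"): 800.0, ("B", "C"): 400.0},
        )
        ch = compute_edge_channels(
            net, tiny_expr.subset({"A", "B", "C"}), tiny_ann,
            cooc=None, params=FusionParams(component_norm="none"),
        )
        assert ch.S == pytest.approx([1.0, 0.5])  # rescaled by the maximum


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    c=st.floats(0.01, 1e3),
    mi=st.floats(0.01, 1e3),
    mj=st.floats(0.01, 1e3),
    t=st.floats(0.0, 1.0),
)
def test_credibility_swap_symmetry_property(c, mi, mj, t):
    """S(i,j) must not depend on which gene is called i."""
    tot = mi + mj + c
    a = interaction_credibility(c, mi, mj, tot, t)
    b = interaction_credibility(c, mj, mi, tot, t)
    assert a == pytest.approx(b, rel=1e-9)
    assert a >= 0
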