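import numpy as np
import pytest

from fiprank import (
    AnnotationMap,
    BenchmarkSpec,
    CooccurrenceTable,
    ExpressionMatrix,
    InteractionNetwork,
    SeedSet,
    generate_benchmark,
)


@pytest.fixture
def tiny_net() -> InteractionNetwork:
    return InteractionNetwork(
        nodes=frozenset({"A", "B", "C", "D"}),
        edges={("A", "B"): None, ("B", "C"): None, ("A", "C"): None, ("C", "D"): None},
    )


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    values = rng.normal(size=(4, 6))
    return ExpressionMatrix(
        genes=["A", "B", "C", "D"],
        samples=[f"s{i}" for i in range(6)],
        values=values,
        group=np.array(["control"] * 3 + ["disease"] * 3, dtype=object),
    )


@pytest.fixture
def tiny_ann() -> AnnotationMap:
    return AnnotationMap.from_pairs(
        [
            ("A", "GO:1"),
            ("B", "GO:1"),
            ("A", "GO:2"),
            ("B", "GO:2"),
            ("C", "GO:2"),
            ("D", "GO:2"),
            ("C", "GO:3"),
        ]
    )


@pytest.fixture
def tiny_cooc() -> CooccurrenceTable:
    return CooccurrenceTable(
        pair_counts={
            ("A", "B"): (4, 2, 1),
            ("B", "C"): (2, 1, 0),
            ("A", "C"): (1, 1, 1),
        }
    )


@pytest.fixture
def tiny_seeds() -> SeedSet:
    return SeedSet(genes=frozenset({"A"}))


SMALL_SPEC = BenchmarkSpec(
    n_genes=120,
    n_module=12,
    n_seeds_revealed=6,
    n_control=10,
    n_disease=10,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_bench():
    """A reduced planted-module bundle shared across validation tests."""
    return generate_benchmark(SMALL_SPEC)
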