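"""Fully in-silico benchmark generator with a planted disease module.

The generator emulates the statistical structure the prioritization method
assumes: a scale-free interaction network containing a densely wired module,
group-structured expression in which module genes are shifted in disease
samples and share a latent co-expression factor, annotations in which module
genes are preferentially co-annotated, and a literature co-occurrence table
in which module-internal edges co-occur more often. Part of the module is
revealed as seed genes; the remainder is the hidden truth a pipeline run
should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import (
    AnnotationMap,
    CooccurrenceTable,
    ExpressionMatrix,
    InteractionNetwork,
    SeedSet,
    canonical_pair,
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Knobs of the planted-module benchmark.

    The defaults describe a 500-gene universe with a 30-gene disease module,
    15 of which are revealed as seeds; 20 control and 20 disease samples;
    a one-SD disease shift plus a shared latent factor for module genes; and
    a 300-document corpus in which edges co-occur far above background and
    module-internal edges co-occur even more.
    """

    n_genes: int = 500
    n_module: int = 30
    n_seeds_revealed: int = 15
    attachment: int = 3  # preferential-attachment edges per new node
    module_density_boost: float = 5.0
    n_control: int = 20
    n_disease: int = 20
    effect_size: float = 1.0  # disease shift of module genes, in noise SDs
    noise_sd: float = 1.0
    latent_sd: float = 0.7  # shared-factor loading of module genes
    n_terms: int = 150
    n_module_terms: int = 5
    module_term_enrichment: float = 0.5
    mean_terms_per_gene: float = 3.0
    corpus_docs: int = 300  # b: number of documents mined
    edge_cooc_rate: float = 0.08
    nonedge_cooc_rate: float = 0.01
    module_cooc_boost: float = 3.0
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.n_module < self.n_genes:
            raise ValueError("need 0 < n_module < n_genes")
        if not 0 < self.n_seeds_revealed <= self.n_module:
            raise ValueError("revealed seeds must be a nonempty subset of the module")
        if self.module_density_boost < 1:
            raise ValueError("module_density_boost must be >= 1")
        for name in ("module_term_enrichment", "edge_cooc_rate", "nonedge_cooc_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.module_cooc_boost < 1:
            raise ValueError("module_cooc_boost must be >= 1")
        if min(self.n_control, self.n_disease) < 2:
            raise ValueError("need >= 2 samples per group")

    def null(self) -> "BenchmarkSpec":
        """The no-signal condition: every module-specific effect switched off.

        Expression shift and latent factor are zeroed, module wiring density
        and co-occurrence match the background, and annotations carry no
        module enrichment; only the module labels remain.
        """
        return replace(
            self,
            effect_size=0.0,
            latent_sd=0.0,
            module_density_boost=1.0,
            module_term_enrichment=0.0,
            module_cooc_boost=1.0,
            nonedge_cooc_rate=self.edge_cooc_rate,
        )


@dataclass
class Benchmark:
    """One generated bundle on a single gene universe."""

    spec: BenchmarkSpec
    network: InteractionNetwork
    expression: ExpressionMatrix
    annotations: AnnotationMap
    cooccurrence: CooccurrenceTable
    seeds: SeedSet  # revealed module genes
    hidden: frozenset[str]  # module genes withheld as ground truth
    module: frozenset[str]


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _rng(spec: BenchmarkSpec, salt: int, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.rng_seed + salt)


def generate_network(
    spec: BenchmarkSpec,
    module_genes: frozenset[str] | None = None,
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Scale-free backbone plus boosted wiring inside the module.

    A preferential-attachment graph supplies the heavy-tailed degree
    distribution; module pairs then gain extra edges so the internal density
    is about module_density_boost times the background. Components, should
    any arise, are bridged to keep propagation connected.
    """
    rng = _rng(spec, 1, rng)
    names = _gene_names(spec.n_genes)
    g = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    if module_genes is None:
        module_genes = frozenset(rng.choice(names, size=spec.n_module, replace=False))
    module = sorted(module_genes)

    p_bg = 2.0 * spec.attachment / (spec.n_genes - 1)
    p_extra = min(0.95, (spec.module_density_boost - 1.0) * p_bg)
    if p_extra > 0:
        for i, a in enumerate(module):
            for b in module[i + 1 :]:
                if not g.has_edge(a, b) and rng.random() < p_extra:
                    g.add_edge(a, b)

    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    for comp in comps[1:]:  # bridge stray components into the giant one
        a = sorted(comp)[0]
        b = sorted(comps[0])[0]
        g.add_edge(a, b)

    edges = {canonical_pair(a, b): None for a, b in g.edges() if a != b}
    return InteractionNetwork(nodes=frozenset(names), edges=edges)


def generate_expression(
    spec: BenchmarkSpec,
    module_genes: frozenset[str],
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Gaussian background; module genes get a latent factor and a disease shift."""
    rng = _rng(spec, 2, rng)
    names = _gene_names(spec.n_genes)
    h = spec.n_control + spec.n_disease
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, h))
    module_idx = [i for i, g in enumerate(names) if g in module_genes]
    if module_idx:
        if spec.latent_sd > 0:
            factor = rng.normal(0.0, 1.0, size=h)
            values[module_idx] += spec.latent_sd * factor
        if spec.effect_size != 0.0:
            values[np.ix_(module_idx, range(spec.n_control, h))] += (
                spec.effect_size * spec.noise_sd
            )
    samples = [f"C{i:03d}" for i in range(1, spec.n_control + 1)] + [
        f"D{i:03d}" for i in range(1, spec.n_disease + 1)
    ]
    group = np.array(
        ["control"] * spec.n_control + ["disease"] * spec.n_disease, dtype=object
    )
    return ExpressionMatrix(genes=names, samples=samples, values=values, group=group)


def generate_annotations(
    spec: BenchmarkSpec,
    module_genes: frozenset[str],
    rng: np.random.Generator | None = None,
) -> AnnotationMap:
    """Random gene-term assignment plus module-specific co-annotation."""
    rng = _rng(spec, 3, rng)
    names = _gene_names(spec.n_genes)
    terms = [f"GO:{i:07d}" for i in range(1, spec.n_terms + 1)]
    module_terms = [f"GO:{9000000 + i:07d}" for i in range(1, spec.n_module_terms + 1)]
    pairs: list[tuple[str, str]] = []
    for g in names:
        k = 1 + rng.poisson(max(spec.mean_terms_per_gene - 1.0, 0.0))
        k = min(k, spec.n_terms)
        for t in rng.choice(terms, size=k, replace=False):
            pairs.append((g, str(t)))
    if spec.module_term_enrichment > 0:
        for g in sorted(module_genes):
            for t in module_terms:
                if rng.random() < spec.module_term_enrichment:
                    pairs.append((g, t))
    return AnnotationMap.from_pairs(pairs)


def generate_cooccurrence(
    spec: BenchmarkSpec,
    net: InteractionNetwork,
    module_genes: frozenset[str] = frozenset(),
    rng: np.random.Generator | None = None,
) -> CooccurrenceTable:
    """Binomial document co-mentions; thinned paragraph and sentence counts.

    True edges co-occur at edge_cooc_rate per document (module-internal edges
    at module_cooc_boost times that), non-edges at the lower background rate.
    Paragraph counts are binomially thinned from document counts and sentence
    counts from paragraph counts, so the containment hierarchy holds by
    construction. As many random non-edge pairs as there are edges are
    sampled; pairs that never co-occur are not stored.
    """
    rng = _rng(spec, 4, rng)
    b = spec.corpus_docs
    counts: dict[tuple[str, str], tuple[int, int, int]] = {}

    def draw(pair: tuple[str, str], rate: float) -> None:
        nd = int(rng.binomial(b, min(rate, 1.0)))
        if nd == 0:
            return
        npar = int(rng.binomial(nd, 0.6))
        ns = int(rng.binomial(npar, 0.4))
        counts[pair] = (nd, npar, ns)

    edges = sorted(net.edges)
    for pair in edges:
        rate = spec.edge_cooc_rate
        if pair[0] in module_genes and pair[1] in module_genes:
            rate *= spec.module_cooc_boost
        draw(pair, rate)

    if spec.nonedge_cooc_rate > 0 and edges:
        nodes = sorted(net.nodes)
        edge_set = set(edges)
        target = len(edges)
        seen: set[tuple[str, str]] = set()
        attempts = 0
        while len(seen) < target and attempts < 20 * target:
            attempts += 1
            a, b2 = rng.choice(nodes, size=2, replace=False)
            pair = canonical_pair(str(a), str(b2))
            if pair in edge_set or pair in seen:
                continue
            seen.add(pair)
            draw(pair, spec.nonedge_cooc_rate)

    return CooccurrenceTable(pair_counts=counts)


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate all components on one universe; fully seed-deterministic."""
    master = np.random.default_rng(spec.rng_seed)
    names = _gene_names(spec.n_genes)
    module = frozenset(master.choice(names, size=spec.n_module, replace=False))
    revealed = frozenset(
        master.choice(sorted(module), size=spec.n_seeds_revealed, replace=False)
    )
    net = generate_network(spec, module, rng=np.random.default_rng(master.integers(2**31)))
    expr = generate_expression(spec, module, rng=np.random.default_rng(master.integers(2**31)))
    ann = generate_annotations(spec, module, rng=np.random.default_rng(master.integers(2**31)))
    cooc = generate_cooccurrence(
        spec, net, module, rng=np.random.default_rng(master.integers(2**31))
    )
    return Benchmark(
        spec=spec,
        network=net,
        expression=expr,
        annotations=ann,
        cooccurrence=cooc,
        seeds=SeedSet(genes=revealed),
        hidden=module - revealed,
        module=module,
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the package's standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "annotations": outdir / "annotations.tsv",
        "cooccurrence": outdir / "cooccurrence.tsv",
        "seeds": outdir / "seeds.txt",
        "hidden": outdir / "hidden_truth.txt",
    }
    with open(paths["network"], "w") as fh:
        for a, b in sorted(bench.network.edges):
            fh.write(f"{a}\t{b}\n")
    bench.expression.to_frame().to_csv(paths["expression"], sep="\t", float_format="%.10g")
    with open(paths["groups"], "w") as fh:
        for s, g in zip(bench.expression.samples, bench.expression.group):
            fh.write(f"{s}\t{g}\n")
    with open(paths["annotations"], "w") as fh:
        for term in sorted(bench.annotations.term_to_genes):
            for g in sorted(bench.annotations.term_to_genes[term]):
                fh.write(f"{g}\t{term}\n")
    with open(paths["cooccurrence"], "w") as fh:
        for (a, b), (nd, npar, ns) in sorted(bench.cooccurrence.pair_counts.items()):
            fh.write(f"{a}\t{b}\t{nd}\t{npar}\t{ns}\n")
    with open(paths["seeds"], "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(bench.seeds.genes))
    with open(paths["hidden"], "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(bench.hidden))
    return paths
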