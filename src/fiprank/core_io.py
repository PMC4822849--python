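"""Domain types, file readers/writers, and universe harmonization.

All gene identifiers are case-normalized (stored upper-case) so that the
three data sources — interaction network, expression matrix and annotations —
can be intersected without spurious losses from capitalization mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"
GROUP_LABELS = (CONTROL, DISEASE)


def normalize_gene(symbol: str) -> str:
    """Canonical gene identifier: stripped, upper-cased, non-empty."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene identifier")
    return s


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair stored in lexicographic order."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected gene interaction network.

    ``edges`` maps canonical (sorted) gene pairs to an optional precomputed
    confidence (e.g. a STRING-style combined score); ``None`` when the edge
    list carried no third column. No self-loops; every endpoint is a node.
    """

    nodes: frozenset[str]
    edges: dict[tuple[str, str], float | None]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"non-canonical edge ({a!r}, {b!r})")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({a}, {b})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def has_confidence(self) -> bool:
        return bool(self.edges) and all(c is not None for c in self.edges.values())

    def subset(self, keep: Iterable[str]) -> "InteractionNetwork":
        """Induced subnetwork on ``keep``."""
        keep = frozenset(keep)
        edges = {
            pair: conf
            for pair, conf in self.edges.items()
            if pair[0] in keep and pair[1] in keep
        }
        return InteractionNetwork(nodes=self.nodes & keep, edges=edges)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a control/disease grouping."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    group: np.ndarray  # per-sample label in {control, disease}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene rows (collapse probes first)")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")
        bad = set(self.group) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for lbl in GROUP_LABELS:
            if int((self.group == lbl).sum()) < 2:
                raise ValueError(f"need >=2 samples in group {lbl!r}")

    @property
    def h(self) -> int:
        """Total sample count (controls plus disease)."""
        return len(self.samples)

    @property
    def control_mask(self) -> np.ndarray:
        return self.group == CONTROL

    @property
    def disease_mask(self) -> np.ndarray:
        return self.group == DISEASE

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def subset(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = set(keep)
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return ExpressionMatrix(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx],
            group=self.group.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class AnnotationMap:
    """Bidirectional gene <-> GO-term mapping. Term sets are never empty."""

    term_to_genes: dict[str, frozenset[str]]
    gene_to_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
        inverse: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            for g in genes:
                inverse.setdefault(g, set()).add(term)
        frozen = {g: frozenset(ts) for g, ts in inverse.items()}
        if self.gene_to_terms and dict(self.gene_to_terms) != frozen:
            raise ValueError("gene_to_terms is not the inverse of term_to_genes")
        object.__setattr__(self, "gene_to_terms", frozen)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            t2g.setdefault(term, set()).add(normalize_gene(gene))
        return cls(term_to_genes={t: frozenset(g) for t, g in t2g.items()})

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def term_size(self, term: str) -> int:
        if term not in self.term_to_genes:
            raise KeyError(f"unknown term {term!r}")
        return len(self.term_to_genes[term])


@dataclass(frozen=True)
class CooccurrenceTable:
    """Per-pair literature co-occurrence counts (document, paragraph, sentence).

    A sentence co-mention implies a paragraph and a document co-mention, so
    n_sent <= n_para <= n_doc is enforced at construction. Marginals are
    always recomputed from pair scores, never stored.
    """

    pair_counts: dict[tuple[str, str], tuple[int, int, int]]

    def __post_init__(self) -> None:
        for pair, (nd, npar, ns) in self.pair_counts.items():
            if pair[0] > pair[1]:
                raise ValueError(f"non-canonical pair {pair}")
            if min(nd, npar, ns) < 0:
                raise ValueError(f"negative count for pair {pair}")
            if not (ns <= npar <= nd):
                raise ValueError(
                    f"count hierarchy violated for {pair}: "
                    f"n_sent={ns} n_para={npar} n_doc={nd}"
                )

    def get(self, a: str, b: str) -> tuple[int, int, int]:
        return self.pair_counts.get(canonical_pair(a, b), (0, 0, 0))


@dataclass(frozen=True)
class SeedSet:
    """Genes already known to be disease-associated (positive labels)."""

    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class RankingResult:
    """Per-gene relevance score q and 1-based rank, sorted by descending q.

    Ties receive the average rank; the listing order breaks ties
    lexicographically by gene so output is deterministic.
    """

    entries: pd.DataFrame  # columns: rank, gene, q, is_seed

    COLUMNS = ("rank", "gene", "q", "is_seed")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"missing ranking columns: {sorted(missing)}")
        self.entries = self.entries.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int) -> pd.DataFrame:
        return self.entries.head(k)

    @classmethod
    def from_scores(cls, q: pd.Series, seeds: Iterable[str]) -> "RankingResult":
        from scipy.stats import rankdata

        seeds = frozenset(seeds)
        df = pd.DataFrame({"gene": q.index.astype(str), "q": q.to_numpy(float)})
        df["rank"] = rankdata(-df["q"].to_numpy(), method="average")
        df["is_seed"] = df["gene"].isin(seeds)
        df = df.sort_values(["rank", "gene"], kind="mergesort")
        return cls(entries=df[list(cls.COLUMNS)])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, has_confidence: bool | None = None) -> InteractionNetwork:
    """Load a 2- or 3-column whitespace/tab-separated edge list.

    Duplicate edges are merged keeping the maximum confidence; self-loops are
    dropped (their count is logged). ``has_confidence=None`` auto-detects a
    third column.
    """
    path = Path(path)
    nodes: set[str] = set()
    edges: dict[tuple[str, str], float | None] = {}
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            if has_confidence is None:
                has_confidence = len(parts) == 3
            if has_confidence and len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: confidence column missing")
            n_lines += 1
            a, b = normalize_gene(parts[0]), normalize_gene(parts[1])
            conf: float | None = None
            if has_confidence:
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad confidence {parts[2]!r}") from exc
                if conf < 0:
                    raise ValueError(f"{path}:{lineno}: negative confidence {conf}")
            nodes.update((a, b))
            if a == b:
                n_self += 1
                continue
            pair = canonical_pair(a, b)
            if pair in edges:
                old = edges[pair]
                if conf is not None:
                    edges[pair] = conf if old is None else max(old, conf)
            else:
                edges[pair] = conf
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self:
        log.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return InteractionNetwork(nodes=frozenset(nodes), edges=edges)


def read_expression(
    path: str | Path,
    group_file: str | Path,
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Load a genes-in-rows TSV expression matrix plus a sample->group map.

    Rows sharing a gene id (multiple probes) are collapsed by ``collapse``
    ("mean", the default, or "max"). Every sample column must appear in the
    two-column group file with a label in {control, disease}.
    """
    if collapse not in ("mean", "max"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    df.index = [normalize_gene(g) for g in df.index]
    df = df.groupby(level=0, sort=True).agg(collapse)

    groups = pd.read_csv(
        group_file, sep="\t", header=None, names=["sample", "label"], dtype=str
    )
    mapping = dict(zip(groups["sample"].str.strip(), groups["label"].str.strip()))
    labels = []
    for s in df.columns:
        if s not in mapping:
            raise ValueError(f"sample {s!r} missing from group file {group_file}")
        lbl = mapping[s]
        if lbl not in GROUP_LABELS:
            raise ValueError(f"sample {s!r} has unknown group label {lbl!r}")
        labels.append(lbl)
    return ExpressionMatrix(
        genes=list(df.index),
        samples=list(df.columns),
        values=df.to_numpy(float),
        group=np.array(labels, dtype=object),
    )


def read_annotations(path: str | Path, format: str = "tsv") -> AnnotationMap:
    """Load gene->GO-term annotations from a 2-column TSV or a GAF 2.x file.

    GAF rows whose qualifier contains ``NOT`` are skipped per the GAF
    specification (they record absence of function).
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if format == "tsv":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                pairs.append((parts[0], parts[1]))
    elif format == "gaf":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                if raw.startswith("!") or not raw.strip():
                    continue
                parts = raw.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: truncated GAF row")
                symbol, qualifier, term = parts[2], parts[3], parts[4]
                if "NOT" in qualifier.split("|"):
                    continue
                pairs.append((symbol, term))
    else:
        raise ValueError(f"unknown annotation format {format!r} (use 'tsv' or 'gaf')")
    return AnnotationMap.from_pairs(pairs)


def read_cooccurrence(path: str | Path) -> CooccurrenceTable:
    """Load a 5-column TSV: gene_a, gene_b, n_doc, n_para, n_sent."""
    path = Path(path)
    counts: dict[tuple[str, str], tuple[int, int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            pair = canonical_pair(normalize_gene(parts[0]), normalize_gene(parts[1]))
            try:
                nd, npar, ns = (int(x) for x in parts[2:5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
            if pair in counts:
                prev = counts[pair]
                nd, npar, ns = (max(p, c) for p, c in zip(prev, (nd, npar, ns)))
            counts[pair] = (nd, npar, ns)
    return CooccurrenceTable(pair_counts=counts)


def read_seeds(path: str | Path) -> SeedSet:
    """Load a one-gene-per-line seed list."""
    genes = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(normalize_gene(line.split()[0]))
    return SeedSet(genes=frozenset(genes))


def write_ranking(result: RankingResult, path: str | Path) -> None:
    """Write a ranking as TSV (rank, gene, q, is_seed); full float precision."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tq\tis_seed\n")
        for row in result.entries.itertuples(index=False):
            fh.write(f"{row.rank:.17g}\t{row.gene}\t{row.q:.17g}\t{int(row.is_seed)}\n")


def read_ranking(path: str | Path) -> RankingResult:
    df = pd.read_csv(path, sep="\t")
    df["is_seed"] = df["is_seed"].astype(bool)
    return RankingResult(entries=df)


# ---------------------------------------------------------------------------
# Universe harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Harmonized:
    """Network, expression and seeds restricted to a common gene universe."""

    network: InteractionNetwork
    expression: ExpressionMatrix
    seeds: SeedSet
    candidates: frozenset[str]
    dropped_seeds: frozenset[str]

    @property
    def universe(self) -> frozenset[str]:
        return self.seeds.genes | self.candidates


def harmonize_universe(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    seeds: SeedSet,
) -> Harmonized:
    """Restrict everything to universe = network nodes ∩ expression genes.

    Seeds outside the universe are dropped (and logged); candidates are the
    universe minus the surviving seeds. Raises if the universe is empty or if
    no seed survives.
    """
    universe = net.nodes & frozenset(expr.genes)
    if not universe:
        raise ValueError("empty universe: network and expression genes are disjoint")
    kept = seeds.genes & universe
    dropped = seeds.genes - universe
    if dropped:
        log.info("dropped %d seed(s) outside the universe: %s", len(dropped), sorted(dropped))
    if seeds.genes and not kept:
        raise ValueError("all seed genes fall outside the universe")
    return Harmonized(
        network=net.subset(universe),
        expression=expr.subset(universe),
        seeds=SeedSet(genes=kept),
        candidates=frozenset(universe - kept),
        dropped_seeds=frozenset(dropped),
    )
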