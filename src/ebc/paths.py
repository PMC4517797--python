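"""Dependency-path extraction from pre-parsed sentence graphs.

A sentence's dependency parse is a tree whose nodes are the tokens and
whose edges carry grammatical relation labels. For every (drug, gene)
mention pair found by lexicon matching, the unique tree path between the
two tokens — oriented drug → gene, edge directions discarded, endpoint
tokens dropped — is the pair's dependency path: an alternating sequence
[relation, interior word, relation, ..., relation] that serves as one
surface form of the relationship.

Filtering rules applied here: sentences must be 4–50 tokens long
(inclusive); paths containing any relation whose label starts with "conj"
are rejected (parser list-representation artifacts); lexicons contain
single-word terms only and matching is case-insensitive (casefold both
sides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .matrix import TripletRecord

__all__ = [
    "DependencyGraph",
    "DependencyPath",
    "EntityMention",
    "GraphStructureError",
    "ConjPathError",
    "LexiconError",
    "load_lexicon",
    "parse_conll",
    "eligible_sentence",
    "match_entities",
    "extract_path",
    "extract_corpus_paths",
]

MIN_SENTENCE_TOKENS = 4
MAX_SENTENCE_TOKENS = 50


class GraphStructureError(ValueError):
    """The dependency graph is not a tree or the endpoints are disconnected."""


class ConjPathError(ValueError):
    """The extracted path crosses a conj-type dependency and is rejected."""


class LexiconError(ValueError):
    """Malformed lexicon input."""


@dataclass(frozen=True)
class DependencyGraph:
    """Tokens (surface forms, positional order) and labeled dependency edges.

    Edges are (governor index, dependent index, relation label), 0-based.
    """

    words: tuple[str, ...]
    edges: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        for g, d, rel in self.edges:
            if not rel:
                raise ValueError("relation labels must be non-empty")
            for idx in (g, d):
                if not (0 <= idx < len(self.words)):
                    raise ValueError(f"edge index {idx} out of range")

    def as_undirected(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(len(self.words)))
        for g, d, rel in self.edges:
            G.add_edge(g, d, rel=rel)
        return G

    def is_tree(self) -> bool:
        G = self.as_undirected()
        return nx.is_connected(G) and G.number_of_edges() == len(self.words) - 1

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class EntityMention:
    surface: str
    index: int
    entity_class: str  # "drug" | "gene"
    term: str  # lexicon entry matched


@dataclass(frozen=True)
class DependencyPath:
    """Alternating [relation, word, relation, ..., relation], drug → gene."""

    elements: tuple[str, ...]

    def __post_init__(self):
        if len(self.elements) % 2 == 0 or not self.elements:
            raise ValueError("path must alternate relation/word, ending on a relation")

    def canonical(self) -> str:
        """Pipe-delimited key: relations lower-cased, interior words case-folded."""
        parts = [
            el.lower() if i % 2 == 0 else el.casefold()
            for i, el in enumerate(self.elements)
        ]
        return "|".join(parts)

    def __str__(self) -> str:
        return self.canonical()


def load_lexicon(source, stoplist: Iterable[str] | None = None) -> set[str]:
    """Load a one-term-per-line lexicon, casefolded.

    Multi-word entries are rejected (entity names must map to single graph
    nodes); terms appearing in the common-English ``stoplist`` are removed.
    """
    if hasattr(source, "read"):
        terms = source.read().splitlines()
    elif isinstance(source, (str,)) and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            terms = fh.read().splitlines()
    else:
        terms = list(source)
    stop = {s.casefold() for s in stoplist} if stoplist else set()
    lexicon = set()
    for term in terms:
        term = term.strip()
        if not term:
            continue
        if len(term.split()) > 1:
            raise LexiconError(f"multi-word lexicon entry rejected: {term!r}")
        folded = term.casefold()
        if folded not in stop:
            lexicon.add(folded)
    return lexicon


def parse_conll(source) -> list[DependencyGraph]:
    """Read CoNLL-like TSV: token index (1-based), word, governor (0=root),
    relation; sentences separated by blank lines."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    graphs = []
    for block in text.split("\n\n"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        words, edges = [], []
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 4:
                raise ValueError(f"expected 4 TSV fields, got {len(parts)}: {ln!r}")
            idx, word, gov, rel = int(parts[0]), parts[1], int(parts[2]), parts[3]
            if idx != len(words) + 1:
                raise ValueError(f"token indices must be consecutive from 1, got {idx}")
            words.append(word)
            if gov != 0:
                edges.append((gov - 1, idx - 1, rel))
        graphs.append(DependencyGraph(tuple(words), tuple(edges)))
    return graphs


def eligible_sentence(token_count: int) -> bool:
    """True iff the sentence length is within the 4–50 token window (inclusive)."""
    if token_count < 0:
        raise ValueError("token count must be >= 0")
    return MIN_SENTENCE_TOKENS <= token_count <= MAX_SENTENCE_TOKENS


def match_entities(
    graph: DependencyGraph,
    drug_lexicon: set[str],
    gene_lexicon: set[str],
) -> list[EntityMention]:
    """Casefolded string matching of tokens against the two lexicons.

    A token matching both lexicons yields one mention per entity class.
    """
    mentions = []
    for i, word in enumerate(graph.words):
        folded = word.casefold()
        if folded in drug_lexicon:
            mentions.append(EntityMention(word, i, "drug", folded))
        if folded in gene_lexicon:
            mentions.append(EntityMention(word, i, "gene", folded))
    return mentions


def extract_path(
    graph: DependencyGraph,
    drug: EntityMention,
    gene: EntityMention,
) -> DependencyPath:
    """The unique tree path between the two mentions, oriented drug → gene.

    Endpoint tokens are dropped; edge directions are discarded. Raises
    :class:`ConjPathError` if any relation on the path starts with "conj"
    and :class:`GraphStructureError` for non-tree graphs or disconnected
    endpoints.
    """
    if not graph.is_tree():
        raise GraphStructureError("dependency graph is not a tree")
    G = graph.as_undirected()
    try:
        nodes = nx.shortest_path(G, drug.index, gene.index)
    except nx.NetworkXNoPath:  # pragma: no cover - trees are connected
        raise GraphStructureError("mention nodes are disconnected") from None
    if len(nodes) < 2:
        raise GraphStructureError("drug and gene mentions share a token")
    elements: list[str] = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        rel = G.edges[a, b]["rel"]
        if rel.lower().startswith("conj"):
            raise ConjPathError(f"path crosses {rel} dependency")
        elements.append(rel)
        if b != nodes[-1]:
            elements.append(graph.words[b])
    return DependencyPath(tuple(elements))


def extract_corpus_paths(
    graphs: Iterable[DependencyGraph],
    drug_lexicon: set[str],
    gene_lexicon: set[str],
) -> list[TripletRecord]:
    """All (drug, gene, path) triplets over a corpus, counts aggregated.

    Sentences outside the 4–50 token window are skipped; conj-crossing
    paths are dropped; a sentence with d drug and g gene mentions yields at
    most d·g paths. Drug/gene fields of the triplets are the casefolded
    lexicon terms, paths their canonical strings.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for graph in graphs:
        if not eligible_sentence(len(graph)):
            continue
        mentions = match_entities(graph, drug_lexicon, gene_lexicon)
        drugs = [m for m in mentions if m.entity_class == "drug"]
        genes = [m for m in mentions if m.entity_class == "gene"]
        for d in drugs:
            for g in genes:
                if d.index == g.index:
                    continue
                try:
                    path = extract_path(graph, d, g)
                except ConjPathError:
                    continue
                key = (d.term, g.term, path.canonical())
                counts[key] = counts.get(key, 0) + 1
    return [
        TripletRecord(drug, gene, path, c)
        for (drug, gene, path), c in sorted(counts.items())
    ]
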