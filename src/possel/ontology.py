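"""Ontology DAG handling: parsing, annotation propagation, testable gene sets.

A Gene Ontology-style vocabulary is a rooted DAG of terms connected by
``is_a`` and ``part_of`` edges (child -> parent).  Genes are annotated to
specific terms and the annotation is propagated to every ancestor, so a
parent's gene set always contains each child's set.  Enrichment testing uses
only terms with enough annotated genes in the scored background (default:
more than 10), and the elim decorrelation procedure processes terms
deepest-first, where depth is the longest path from the namespace root so a
term is always visited before all of its ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Edge types that propagate annotation by default.
DEFAULT_RELATIONS = ("is_a", "part_of")

#: "more than 10 genes" -> at least 11 members.
DEFAULT_MIN_SIZE = 11


@dataclass
class OntologyGraph:
    """Term DAG with child->parent edges restricted to a relation whitelist.

    Attributes
    ----------
    graph
        ``networkx.DiGraph`` with one edge child -> parent per retained
        relation; node attributes ``name`` and ``namespace``.
    depth
        Longest-path distance from the namespace root (root depth 0).
    """

    graph: nx.DiGraph
    depth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph contains a cycle, e.g. edge {cycle[0]}")
        if not self.depth:
            self.depth = _longest_path_depths(self.graph)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable along child->parent edges (excluding term itself)."""
        return nx.descendants(self.graph, term)

    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    @classmethod
    def from_obo(
        cls,
        path_or_handle,
        relations: Iterable[str] = DEFAULT_RELATIONS,
    ) -> "OntologyGraph":
        """Parse an OBO file (subset: [Term] stanzas; obsolete terms skipped).

        obonet returns a MultiDiGraph with child->parent edges keyed by
        relation type; edges outside the whitelist are dropped.
        """
        multi = obonet.read_obo(path_or_handle, ignore_obsolete=True)
        keep = set(relations)
        g = nx.DiGraph()
        for node, attrs in multi.nodes(data=True):
            g.add_node(node, name=attrs.get("name", node),
                       namespace=attrs.get("namespace", ""))
        for u, v, key in multi.edges(keys=True):
            if key in keep:
                g.add_edge(u, v, relation=key)
        return cls(graph=g)


def _longest_path_depths(graph: nx.DiGraph) -> dict[str, int]:
    """Depth(term) = longest path to term from its namespace root.

    Computed as the longest path FROM a root in the reversed (parent->child)
    orientation, by dynamic programming in topological order.
    """
    rev = graph.reverse(copy=False)
    depth: dict[str, int] = {}
    for node in nx.topological_sort(rev):
        preds = list(rev.predecessors(node))
        depth[node] = 0 if not preds else 1 + max(depth[p] for p in preds)
    return depth


@dataclass
class GeneSetCollection:
    """Per-term propagated gene sets over a scored background."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str]
    min_size: int = DEFAULT_MIN_SIZE
    namespaces: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def size(self, term: str) -> int:
        return len(self.sets[term])


def propagate(
    graph: OntologyGraph,
    gene_to_terms: Iterable[tuple[str, str]] | pd.DataFrame,
) -> GeneSetCollection:
    """Propagate gene annotations to all ancestor terms.

    Parameters
    ----------
    graph
        The ontology DAG.
    gene_to_terms
        Iterable of ``(gene, term)`` pairs or a DataFrame with columns
        ``gene`` and ``term``.  Pairs referencing unknown terms are skipped
        with a warning.

    Returns
    -------
    A :class:`GeneSetCollection` with closed sets (parent set contains each
    child set) and background = all annotated genes.  No size filter is
    applied here; see :func:`filter_sets`.
    """
    if isinstance(gene_to_terms, pd.DataFrame):
        pairs = list(zip(gene_to_terms["gene"], gene_to_terms["term"]))
    else:
        pairs = list(gene_to_terms)

    sets: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    skipped = 0
    for gene, term in pairs:
        if term not in graph.graph:
            skipped += 1
            continue
        if term not in anc_cache:
            anc_cache[term] = graph.ancestors(term) | {term}
        for t in anc_cache[term]:
            sets.setdefault(t, set()).add(gene)
    if skipped:
        logger.warning("propagate: skipped %d association(s) to unknown terms", skipped)

    background = frozenset(g for s in sets.values() for g in s)
    return GeneSetCollection(
        sets={t: frozenset(s) for t, s in sets.items()},
        background=background,
        namespaces={t: graph.namespace(t) for t in sets},
    )


def filter_sets(
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    background: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Restrict sets to a background and keep terms with >= min_size members.

    ``min_size`` follows the "more than 10 genes" convention: a term is
    retained iff it maps to at least ``min_size`` (> min_size - 1) background
    genes; membership is intersected with the background.
    """
    bg = frozenset(background) if background is not None else collection.background
    if not bg:
        raise ValueError("background must be nonempty")
    filtered = {}
    for term, genes in collection.sets.items():
        inter = genes & bg
        if len(inter) >= min_size:
            filtered[term] = frozenset(inter)
    return GeneSetCollection(
        sets=filtered,
        background=bg,
        min_size=min_size,
        namespaces={t: collection.namespaces.get(t, "") for t in filtered},
    )


def depth_order(graph: OntologyGraph, terms: Iterable[str] | None = None) -> list[str]:
    """Terms sorted deepest-first; ties broken lexicographically by term id."""
    pool = list(terms) if terms is not None else graph.terms
    return sorted(pool, key=lambda t: (-graph.depth[t], t))
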