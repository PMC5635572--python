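"""Transitive closure of is-a over non-obsolete terms.

The enrichment method compares synonyms of every hierarchically related
pair of terms — ancestors and descendants connected directly or through
chains of is-a edges — within each top-level category of the ontology.
Terms reachable from several categories contribute in each; the union is
deduplicated, so category scoping only affects traversal, not the global
pair set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .obo_io import OntologyModel, OntologyValidationError

__all__ = ["ClosurePair", "parent_graph", "descendant_pairs", "all_closure_pairs"]


@dataclass(frozen=True, order=True)
class ClosurePair:
    """An (ancestor, descendant) pair with the length of the shortest
    is-a path between them (1 = direct parent)."""

    ancestor_id: str
    descendant_id: str
    min_depth: int


def parent_graph(model: OntologyModel) -> nx.DiGraph:
    """Directed graph with an edge parent -> child for every is_a edge
    between non-obsolete terms."""
    g = nx.DiGraph()
    alive = {t.id for t in model.non_obsolete()}
    g.add_nodes_from(alive)
    for t in model.non_obsolete():
        for p in t.parents:
            if p in alive:
                g.add_edge(p, t.id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(a for a, _ in cycle) + f" -> {cycle[0][0]}"
        raise OntologyValidationError(f"is_a cycle: {path}")
    return g


def descendant_pairs(
    model: OntologyModel, category_root: str, graph: nx.DiGraph | None = None
) -> set[ClosurePair]:
    """All ancestor/descendant pairs in the sub-DAG rooted at
    ``category_root``, from the category root down to the leaves."""
    g = graph if graph is not None else parent_graph(model)
    if category_root not in g:
        raise OntologyValidationError(
            f"unknown or obsolete category root {category_root!r}"
        )
    nodes = {category_root} | nx.descendants(g, category_root)
    sub = g.subgraph(nodes)
    pairs: set[ClosurePair] = set()
    for anc in nodes:
        for desc, depth in nx.single_source_shortest_path_length(sub, anc).items():
            if depth >= 1:
                pairs.add(ClosurePair(anc, desc, depth))
    return pairs


def all_closure_pairs(
    model: OntologyModel, categories: list[str] | None = None
) -> set[ClosurePair]:
    """Union of closure pairs over the top-level categories, deduplicated.

    Shortest-path depth within a category sub-DAG equals the global
    shortest-path depth (every path between two terms under a category
    stays under it), so duplicates across categories agree on min_depth.
    """
    g = parent_graph(model)
    cats = categories if categories is not None else model.categories
    pairs: set[ClosurePair] = set()
    for c in cats:
        pairs |= descendant_pairs(model, c, graph=g)
    return pairs
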