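"""Scoring, deduplication and export of computed local alignments.

The ISC (Index of Structural Conservation) summarises how well the aligned
subgraphs' edge structures agree under the row mapping: for every network pair a
Dice coefficient of conserved edges, averaged over pairs and reported as a
percentage.  The overlap filter discards, of any two alignments sharing more than
an allowed fraction of nodes, the smaller one.  The alignment-graph builder merges
an alignment into a single exportable graph with solid, weight-coloured
intra-edges and dashed inter-edges.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import networkx as nx

from .core import Alignment
from .io_formats import AnnotationStore, PPINetwork, GO_NAMESPACES

__all__ = [
    "isc_score",
    "overlap_fraction",
    "filter_overlap",
    "filter_min_size",
    "weight_color",
    "build_alignment_graph",
    "write_alignment_graph",
]


def _induced_edges(alignment: Alignment, networks: Sequence[PPINetwork], index: int) -> set[frozenset]:
    column = set(alignment.column(index))
    graph = networks[index].graph
    return {
        frozenset((u, v)) for u, v in graph.edges if u in column and v in column
    }


def isc_score(alignment: Alignment, networks: Sequence[PPINetwork]) -> float:
    """Average pairwise structural conservation, as a percentage in [0, 100].

    For each unordered network pair (i, j), subgraph i's induced edges are mapped
    through the row correspondence into network j's label space; the pair scores
    the Dice coefficient ``2·|conserved| / (|E_i| + |E_j|)``, defined as 1 when
    both induced edge sets are empty.  Returns 0 below 2 rows by convention.
    """
    if len(alignment.rows) < 2:
        return 0.0
    n = len(alignment.network_ids)
    edge_sets = [_induced_edges(alignment, networks, i) for i in range(n)]
    pair_scores = []
    for i, j in combinations(range(n), 2):
        mapping = {row[i]: row[j] for row in alignment.rows}
        e_i, e_j = edge_sets[i], edge_sets[j]
        if not e_i and not e_j:
            pair_scores.append(1.0)
            continue
        mapped = {frozenset(mapping[u] for u in edge) for edge in e_i}
        conserved = mapped & e_j
        pair_scores.append(2.0 * len(conserved) / (len(e_i) + len(e_j)))
    return 100.0 * sum(pair_scores) / len(pair_scores)


def overlap_fraction(a: Alignment, b: Alignment) -> float:
    """Fraction of the smaller alignment's nodes shared with the other.

    "Smaller" means fewer rows; ties go by total node count, then by argument
    order (the second alignment is treated as the later-discovered one).
    """
    nodes_a, nodes_b = a.node_set(), b.node_set()
    shared = len(nodes_a & nodes_b)
    if len(a.rows) != len(b.rows):
        smaller = nodes_a if len(a.rows) < len(b.rows) else nodes_b
    elif len(nodes_a) != len(nodes_b):
        smaller = min(nodes_a, nodes_b, key=len)
    else:
        smaller = nodes_b
    if not smaller:
        return 0.0
    return shared / len(smaller)


def filter_overlap(alignments: list[Alignment], overlap: float) -> list[Alignment]:
    """Keep alignments whose overlap with every larger kept one is <= *overlap*.

    Alignments are processed in descending size (stable in discovery order), so
    of any conflicting pair the smaller/later one is the one discarded.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    ordered = sorted(alignments, key=lambda a: -len(a.rows))
    kept: list[Alignment] = []
    for candidate in ordered:
        if all(overlap_fraction(survivor, candidate) <= overlap for survivor in kept):
            kept.append(candidate)
    return kept


def filter_min_size(alignments: list[Alignment], min_complex_size: int) -> list[Alignment]:
    """Keep exactly the alignments with at least *min_complex_size* rows."""
    if min_complex_size < 1:
        raise ValueError("min_complex_size must be at least 1")
    return [a for a in alignments if len(a.rows) >= min_complex_size]


def weight_color(weight: float) -> str:
    """Colour class of an intra-edge by fixed tertiles of the [0, 1] weight range:
    green below 1/3, yellow below 2/3, red at and above 2/3."""
    if weight < 1.0 / 3.0:
        return "green"
    if weight < 2.0 / 3.0:
        return "yellow"
    return "red"


def _node_key(network_id: str, protein: str) -> str:
    return f"{protein}@{network_id}"


def build_alignment_graph(
    alignment: Alignment,
    networks: Sequence[PPINetwork],
    annotations: Optional[AnnotationStore] = None,
) -> nx.Graph:
    """Merge an alignment into one graph for export or display.

    Nodes are (protein, network) pairs keyed ``protein@network``.  Intra-edges
    are the induced within-network interactions (solid, coloured by weight
    tertile); inter-edges join the members of each row pairwise across networks
    (dashed), so each row contributes C(N, 2) of them.  Annotations, when given,
    decorate the nodes and change nothing else.
    """
    graph = nx.Graph()
    n = len(alignment.network_ids)
    for i, net in enumerate(alignment.network_ids):
        for protein in alignment.column(i):
            attrs = {"protein": protein, "network": net, "description": ""}
            if annotations is not None:
                attrs["description"] = annotations.description(protein)
                for namespace in GO_NAMESPACES:
                    terms = annotations.terms(protein, namespace)
                    if terms:
                        attrs[f"go_{namespace}"] = ";".join(terms)
            graph.add_node(_node_key(net, protein), **attrs)
    for i, net in enumerate(networks):
        column = set(alignment.column(i))
        for u, v in net.graph.edges:
            if u in column and v in column:
                graph.add_edge(
                    _node_key(net.network_id, u),
                    _node_key(net.network_id, v),
                    kind="intra",
                    weight=float(net.graph[u][v]["weight"]),
                    color=weight_color(net.graph[u][v]["weight"]),
                    style="solid",
                )
    for row in alignment.rows:
        for i, j in combinations(range(n), 2):
            graph.add_edge(
                _node_key(alignment.network_ids[i], row[i]),
                _node_key(alignment.network_ids[j], row[j]),
                kind="inter",
                style="dashed",
            )
    return graph


def write_alignment_graph(graph: nx.Graph, path) -> None:
    """Serialise an alignment graph as GraphML."""
    nx.write_graphml(graph, path)
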