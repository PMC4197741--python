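"""Independent brute-force oracles and small random instance generators.

These deliberately use naive enumeration (edge-by-edge pair counting, fixed-point
pairwise elimination) so they share no search logic with the implementation they
cross-check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from gasoline import Alignment, PPINetwork, overlap_fraction


def brute_force_isc(alignment: Alignment, networks) -> float:
    """ISC by exhaustive edge-pair comparison per network pair."""
    if len(alignment.rows) < 2:
        return 0.0
    n = len(alignment.network_ids)
    columns = [set(alignment.column(i)) for i in range(n)]
    edge_lists = []
    for i, net in enumerate(networks):
        edge_lists.append(
            [(u, v) for u, v in net.graph.edges if u in columns[i] and v in columns[i]]
        )
    scores = []
    for i, j in combinations(range(n), 2):
        mapping = {row[i]: row[j] for row in alignment.rows}
        e_i, e_j = edge_lists[i], edge_lists[j]
        if not e_i and not e_j:
            scores.append(1.0)
            continue
        conserved = 0
        for (u, v) in e_i:
            for (x, y) in e_j:
                if {mapping[u], mapping[v]} == {x, y}:
                    conserved += 1
                    break
        scores.append(2.0 * conserved / (len(e_i) + len(e_j)))
    return 100.0 * sum(scores) / len(scores)


def fixed_point_overlap_filter(alignments, overlap: float):
    """Apply the discard rule over all pairs until a fixed point.

    Pairs are examined with the larger (earlier-discovered on ties) alignment
    first; of a conflicting live pair the smaller/later one is discarded.
    """
    order = sorted(range(len(alignments)), key=lambda i: -len(alignments[i].rows))
    alive = set(order)
    changed = True
    while changed:
        changed = False
        for a_pos in range(len(order)):
            for b_pos in range(a_pos + 1, len(order)):
                ia, ib = order[a_pos], order[b_pos]
                if ia in alive and ib in alive:
                    if overlap_fraction(alignments[ia], alignments[ib]) > overlap:
                        alive.discard(ib)
                        changed = True
    return [alignments[i] for i in order if i in alive]


def random_alignment_instance(
    rng: np.random.Generator,
    n_networks: int,
    n_rows: int,
    extra_nodes: int = 3,
    edge_prob: float = 0.4,
):
    """A random alignment over freshly built random weighted networks."""
    networks = []
    rows = [tuple(f"r{k}_n{i}" for i in range(n_networks)) for k in range(n_rows)]
    for i in range(n_networks):
        nodes = [row[i] for row in rows] + [f"x{j}_n{i}" for j in range(extra_nodes)]
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        for u, v in combinations(nodes, 2):
            if rng.random() < edge_prob:
                graph.add_edge(u, v, weight=float(rng.uniform(0.0, 1.0)))
        networks.append(PPINetwork(network_id=f"net{i}", graph=graph))
    alignment = Alignment(tuple(f"net{i}" for i in range(n_networks)), rows)
    return alignment, networks


def random_alignment_family(
    rng: np.random.Generator, n_alignments: int, n_networks: int = 2, pool: int = 8
):
    """Random small alignments over a shared protein pool, so overlaps occur."""
    ids = tuple(f"net{i}" for i in range(n_networks))
    family = []
    for _ in range(n_alignments):
        k = int(rng.integers(1, 6))
        columns = []
        for i in range(n_networks):
            proteins = [f"p{j}_n{i}" for j in range(pool)]
            chosen = rng.choice(pool, size=k, replace=False)
            columns.append([proteins[c] for c in chosen])
        rows = [tuple(col[r] for col in columns) for r in range(k)]
        family.append(Alignment(ids, rows))
    return family
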