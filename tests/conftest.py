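from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from gasoline import (
    Alignment,
    FixtureSpec,
    PlantedComplex,
    PPINetwork,
    SimilarityStore,
    generate_fixture,
)


def make_network(network_id: str, weighted_edges) -> PPINetwork:
    graph = nx.Graph()
    for u, v, w in weighted_edges:
        graph.add_edge(u, v, weight=w)
    return PPINetwork(network_id=network_id, graph=graph)


@pytest.fixture
def clique_pair():
    """Two networks each holding a 5-clique with weights (i+j)/10 on edge (i, j),
    one weakly attached background node, and identity similarity of 100 between
    counterpart clique members.  Built so every clique row raises the extension
    objective while the background row cannot."""
    networks = []
    for label, prefix in (("netA", "a"), ("netB", "b")):
        edges = [
            (f"{prefix}{i}", f"{prefix}{j}", (i + j) / 10.0)
            for i, j in combinations(range(1, 6), 2)
        ]
        edges.append((f"{prefix}1", f"{prefix}_bg", 0.05))
        networks.append(make_network(label, edges))
    sim = SimilarityStore("bitscore")
    for i in range(1, 6):
        sim.add_pair(f"a{i}", f"b{i}", 100.0)
    truth_rows = [(f"a{i}", f"b{i}") for i in range(1, 6)]
    return networks, sim, truth_rows


@pytest.fixture
def small_fixture():
    """A light planted-complex fixture for fast end-to-end runs."""
    spec = FixtureSpec(
        background_nodes=30,
        planted_complexes=[PlantedComplex(size=5)],
        rng_seed=11,
    )
    return generate_fixture(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def alignment_of(rows, network_ids=("netA", "netB")):
    return Alignment(tuple(network_ids), [tuple(r) for r in rows])
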