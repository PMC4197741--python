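"""Synthetic network families with planted conserved complexes.

The generator emulates the aligner's study conditions with no downloads: each
network is an Erdős–Rényi background graph with light edge weights, into which one
or more conserved complexes are planted as heavy quasi-cliques whose member nodes
have designated counterparts in every network.  A matching bit-score similarity
links counterparts strongly and adds weaker random decoy pairs; annotation and
orthology-group files can be written in the exact input dialects, so fixtures
double as format documentation.

Counterpart node ``k`` of complex ``c`` in network ``i`` is named ``C{c}_N{i}_P{k}``,
making the ground truth self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import Alignment
from .io_formats import (
    AnnotationStore,
    PPINetwork,
    SimilarityStore,
    write_annotation_file,
    write_bitscore_file,
    write_cog_file,
    write_network_file,
)
import networkx as nx

__all__ = [
    "PlantedComplex",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "write_fixture",
    "score_recovery",
    "Recovery",
    "generate_seed_instance",
    "brute_force_best_row",
]

_GO_POOL = [
    ("C", "GO:0005737"),
    ("C", "GO:0005634"),
    ("P", "GO:0006281"),
    ("P", "GO:0006412"),
    ("F", "GO:0003677"),
    ("F", "GO:0004672"),
]


@dataclass(frozen=True)
class PlantedComplex:
    """One conserved complex: *size* counterpart nodes per network, wired with
    intra-edge probability *edge_prob* and weights drawn from *weight_range*."""

    size: int = 6
    edge_prob: float = 0.9
    weight_range: tuple[float, float] = (0.7, 1.0)


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic fixture.

    Defaults: three 60-node networks with Erdős–Rényi background density 0.05 and
    light weights in [0.1, 0.5]; two planted size-6 complexes wired at 0.9 with
    heavy weights in [0.7, 1.0]; counterpart bit score 200 against random decoy
    pairs scoring at most 20 (one decoy per background node per network pair).
    Plantings are detectable by construction: the complexes are denser than the
    background and counterpart similarity exceeds every decoy score.
    """

    n_networks: int = 3
    background_nodes: int = 60
    background_edge_prob: float = 0.05
    planted_complexes: list[PlantedComplex] = field(
        default_factory=lambda: [PlantedComplex(), PlantedComplex()]
    )
    planted_similarity: float = 200.0
    decoy_similarity: tuple[float, float] = (0.0, 20.0)
    decoy_pairs_per_network_pair: Optional[int] = None
    background_weight_range: tuple[float, float] = (0.1, 0.5)
    rng_seed: int = 0

    def __post_init__(self):
        self.planted_complexes = [
            c if isinstance(c, PlantedComplex) else PlantedComplex(*c)
            for c in self.planted_complexes
        ]
        if self.n_networks < 2:
            raise ValueError("need at least two networks")
        total_planted = sum(c.size for c in self.planted_complexes)
        if total_planted > self.background_nodes:
            raise ValueError(
                f"planted nodes ({total_planted}) exceed background_nodes ({self.background_nodes})"
            )
        for c in self.planted_complexes:
            if c.edge_prob <= self.background_edge_prob:
                raise ValueError("planted edge probability must exceed the background's")
        if self.planted_similarity <= self.decoy_similarity[1]:
            raise ValueError("planted similarity must exceed the maximum decoy similarity")


class Fixture(NamedTuple):
    networks: list[PPINetwork]
    similarity: SimilarityStore
    annotations: AnnotationStore
    truth_rows: list[tuple[str, ...]]


def _network_nodes(spec: FixtureSpec, network_index: int) -> list[str]:
    """Node names of one network: planted counterparts first, then background."""
    names: list[str] = []
    for c, complex_ in enumerate(spec.planted_complexes, start=1):
        names.extend(f"C{c}_N{network_index}_P{k}" for k in range(complex_.size))
    n_background = spec.background_nodes - len(names)
    names.extend(f"N{network_index}_B{j}" for j in range(n_background))
    return names


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build networks, similarity, annotations and ground-truth rows from *spec*.

    Deterministic given ``spec.rng_seed``.  Nodes left isolated by the random
    wiring are dropped so the networks honour the edge-list invariant (the node
    set equals the set of edge endpoints).
    """
    rng = np.random.default_rng(spec.rng_seed)
    low_w, high_w = spec.background_weight_range
    networks: list[PPINetwork] = []
    for i in range(1, spec.n_networks + 1):
        names = _network_nodes(spec, i)
        graph = nx.Graph()
        graph.add_nodes_from(names)
        for u, v in combinations(names, 2):
            if rng.random() < spec.background_edge_prob:
                graph.add_edge(u, v, weight=float(rng.uniform(low_w, high_w)))
        offset = 0
        for complex_ in spec.planted_complexes:
            members = names[offset : offset + complex_.size]
            offset += complex_.size
            lo, hi = complex_.weight_range
            for u, v in combinations(members, 2):
                if graph.has_edge(u, v):
                    graph.remove_edge(u, v)
                if rng.random() < complex_.edge_prob:
                    graph.add_edge(u, v, weight=float(rng.uniform(lo, hi)))
        graph.remove_nodes_from([n for n, d in list(graph.degree) if d == 0])
        networks.append(PPINetwork(network_id=f"net{i}", graph=graph))

    truth_rows: list[tuple[str, ...]] = []
    for c, complex_ in enumerate(spec.planted_complexes, start=1):
        for k in range(complex_.size):
            truth_rows.append(
                tuple(f"C{c}_N{i}_P{k}" for i in range(1, spec.n_networks + 1))
            )

    similarity = SimilarityStore("bitscore")
    for row in truth_rows:
        for u, v in combinations(row, 2):
            similarity.add_pair(u, v, spec.planted_similarity)
    n_decoys = (
        spec.decoy_pairs_per_network_pair
        if spec.decoy_pairs_per_network_pair is not None
        else spec.background_nodes
    )
    lo_d, hi_d = spec.decoy_similarity
    node_lists = [sorted(net.graph.nodes) for net in networks]
    for i, j in combinations(range(spec.n_networks), 2):
        for _ in range(n_decoys):
            u = node_lists[i][rng.integers(len(node_lists[i]))]
            v = node_lists[j][rng.integers(len(node_lists[j]))]
            if similarity.score(u, v) > 0:
                continue
            similarity.add_pair(u, v, float(rng.uniform(lo_d, hi_d)))

    annotations = AnnotationStore()
    for node_list in node_lists:
        for name in node_list:
            annotations.descriptions[name] = f"synthetic protein {name}"
            prefix, term = _GO_POOL[int(rng.integers(len(_GO_POOL)))]
            buckets = {ns: [] for ns in ("cellular_component", "biological_process",
                                         "molecular_function", "unclassified")}
            namespace = {"C": "cellular_component", "P": "biological_process",
                         "F": "molecular_function"}[prefix]
            buckets[namespace].append(term)
            annotations.go_terms[name] = buckets

    return Fixture(networks, similarity, annotations, truth_rows)


def write_fixture(fixture: Fixture, out_dir) -> dict[str, list[str] | str]:
    """Write a fixture in the aligner's input dialects; returns the paths.

    Besides the network, bit-score and GO files, an orthology-group file is
    derived from the ground truth (each counterpart set shares one group, every
    other protein gets a private group), so the COG dialect is exercised too.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network_paths = []
    for net in fixture.networks:
        path = out / f"{net.network_id}.txt"
        write_network_file(net, path)
        network_paths.append(str(path))
    bitscore_path = out / "bitscores.tsv"
    write_bitscore_file(fixture.similarity, bitscore_path)
    groups: dict[str, set[str]] = {}
    for idx, row in enumerate(fixture.truth_rows):
        for protein in row:
            groups.setdefault(protein, set()).add(f"COG{idx:04d}")
    for net in fixture.networks:
        for node in net.graph.nodes:
            groups.setdefault(node, {f"NOG_{node}"})
    cog_path = out / "cogs.txt"
    write_cog_file(groups, cog_path)
    go_path = out / "annotations.txt"
    write_annotation_file(fixture.annotations, go_path)
    return {
        "networks": network_paths,
        "bitscores": str(bitscore_path),
        "cogs": str(cog_path),
        "annotations": str(go_path),
    }


class Recovery(NamedTuple):
    precision: float
    recall: float


def score_recovery(result: Sequence[Alignment], truth: Sequence[tuple[str, ...]]) -> Recovery:
    """Precision/recall of planted rows.

    A truth row is recovered when some result alignment contains it exactly.
    Recall is recovered/|truth|; precision is the fraction of all result rows
    that are truth rows (0 when the result is empty).
    """
    truth_set = set(truth)
    result_rows = [row for alignment in result for row in alignment.rows]
    if not result_rows:
        return Recovery(precision=0.0, recall=0.0)
    recovered = {row for row in result_rows if row in truth_set}
    matched = sum(1 for row in result_rows if row in truth_set)
    recall = len(recovered & truth_set) / len(truth_set) if truth_set else 0.0
    return Recovery(precision=matched / len(result_rows), recall=recall)


# ---------------------------------------------------------------------------
# Small seed-sampler instances with an enumerable optimum
# ---------------------------------------------------------------------------


def generate_seed_instance(
    rng: np.random.Generator,
    n_networks: int = 3,
    n_candidates: int = 5,
    planted_score: float = 100.0,
) -> tuple[list[PPINetwork], SimilarityStore, list[list[str]]]:
    """A tiny instance whose best seed row is checkable by exhaustive enumeration.

    Each network has *n_candidates* nodes on a path (every node has degree >= 1);
    one designated counterpart per network scores *planted_score* pairwise, all
    other cross-network pairs draw decoy scores below 1.
    """
    networks = []
    candidates: list[list[str]] = []
    for i in range(1, n_networks + 1):
        nodes = [f"s{i}_{k}" for k in range(n_candidates)]
        graph = nx.Graph()
        for a, b in zip(nodes, nodes[1:]):
            graph.add_edge(a, b, weight=0.5)
        networks.append(PPINetwork(network_id=f"tiny{i}", graph=graph))
        candidates.append(nodes)
    sim = SimilarityStore("bitscore")
    for i, j in combinations(range(n_networks), 2):
        for a, b in product(candidates[i], candidates[j]):
            sim.add_pair(a, b, float(rng.uniform(0.0, 1.0)))
    for i, j in combinations(range(n_networks), 2):
        sim.add_pair(candidates[i][0], candidates[j][0], planted_score)
    return networks, sim, candidates


def brute_force_best_row(
    candidates: Sequence[Sequence[str]], sim: SimilarityStore
) -> tuple[str, ...]:
    """Exhaustively enumerate every candidate row and return the best-scoring one
    (ties broken by enumeration order, i.e. lexicographic in candidate order)."""
    from .core import row_similarity

    best_row: tuple[str, ...] | None = None
    best_score = -1.0
    for row in product(*candidates):
        score = row_similarity(row, sim)
        if score > best_score:
            best_row, best_score = row, score
    assert best_row is not None
    return best_row
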