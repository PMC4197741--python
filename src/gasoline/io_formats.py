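"""Readers and writers for the plain-text formats consumed and produced by the aligner.

Four input dialects are supported, all whitespace-separated with ``#`` comments:

* **network** — weighted edge list, 2–3 columns ``node node [weight]``.  A missing
  weight defaults to 1.0.  Weights in ``(1, 1000]`` are interpreted as STRING-style
  combined scores and divided by 1000 so every stored weight is an interaction
  probability in ``[0, 1]``.
* **bit scores** — ``protein protein score``: pairwise cross-species BLAST bit scores.
* **COG groups** — ``protein group [group ...]``: orthology-group (COG/KOG/NOG)
  membership; two cross-network proteins are similar when they share groups.
* **GO annotations** — ``protein [description tokens] [GO terms]``: decorative
  protein descriptions and GO term identifiers, never used by the alignment itself.

The single output format is the per-alignment result file written by
:func:`write_alignment_file`: a header (networks, size, density, ISC), one induced
subgraph edge-list block per network, and the one-to-one node mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("gasoline")

__all__ = [
    "PPINetwork",
    "SimilarityStore",
    "AnnotationStore",
    "FileFormatError",
    "load_network",
    "load_similarity_bitscores",
    "load_similarity_cogs",
    "load_annotations",
    "write_network_file",
    "write_bitscore_file",
    "write_cog_file",
    "write_annotation_file",
    "write_alignment_file",
    "read_alignment_file",
    "GO_NAMESPACES",
]

#: GO namespace buckets, in the order they are reported.
GO_NAMESPACES = (
    "cellular_component",
    "biological_process",
    "molecular_function",
    "unclassified",
)

# GOA-style namespace prefixes routing a term to its aspect; bare GO ids are
# syntactically namespace-free and land in "unclassified".
_GO_PREFIX_TABLE = {
    "C": "cellular_component",
    "P": "biological_process",
    "F": "molecular_function",
}

_GO_TOKEN_RE = re.compile(r"^(?:([CPFcpf]):)?(GO:\d+)$")


class FileFormatError(ValueError):
    """Raised for malformed input files; carries the file path and line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")


def _data_lines(path):
    """Yield ``(lineno, line)`` for non-blank, non-comment lines of *path*."""
    try:
        fh = open(path, "r", encoding="utf-8")
    except OSError as exc:
        raise FileFormatError(path, None, f"cannot read file ({exc})") from exc
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPINetwork:
    """One species' undirected, probability-weighted interaction network.

    Wraps a :class:`networkx.Graph` whose edges carry a ``weight`` attribute in
    ``[0, 1]``; the node set is exactly the endpoints seen in the edge list.
    """

    network_id: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def edge_weight(self, u: str, v: str, default: float = 0.0) -> float:
        data = self.graph.get_edge_data(u, v)
        return default if data is None else data["weight"]


def _pair_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class SimilarityStore:
    """Cross-network protein similarity in one of two modes.

    * ``bitscore`` — explicit pairwise scores; unlisted pairs score 0.
    * ``cog`` — orthology-group membership; the implied pairwise score is the
      number of shared groups.
    """

    def __init__(self, mode: str):
        if mode not in ("bitscore", "cog"):
            raise ValueError(f"unknown similarity mode: {mode!r}")
        self.mode = mode
        self.pair_scores: dict[tuple[str, str], float] = {}
        self.group_membership: dict[str, frozenset[str]] = {}

    def add_pair(self, u: str, v: str, score: float) -> None:
        if score < 0 or not score == score or score in (float("inf"),):
            raise ValueError(f"similarity score must be a finite non-negative number, got {score}")
        self.pair_scores[_pair_key(u, v)] = float(score)

    def add_groups(self, protein: str, groups: Iterable[str]) -> None:
        merged = self.group_membership.get(protein, frozenset()) | frozenset(groups)
        self.group_membership[protein] = merged

    def score(self, u: str, v: str) -> float:
        if self.mode == "bitscore":
            return self.pair_scores.get(_pair_key(u, v), 0.0)
        gu = self.group_membership.get(u)
        gv = self.group_membership.get(v)
        if not gu or not gv:
            return 0.0
        return float(len(gu & gv))

    def __len__(self) -> int:
        return len(self.pair_scores) if self.mode == "bitscore" else len(self.group_membership)


@dataclass
class AnnotationStore:
    """Decorative protein descriptions and GO terms, keyed by namespace.

    Annotations never influence alignment results; they are only attached to
    exported alignment graphs.
    """

    descriptions: dict[str, str] = field(default_factory=dict)
    go_terms: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def terms(self, protein: str, namespace: str) -> list[str]:
        return self.go_terms.get(protein, {}).get(namespace, [])

    def description(self, protein: str) -> str:
        return self.descriptions.get(protein, "")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_network(path, network_id: str) -> PPINetwork:
    """Parse a weighted edge-list file into a :class:`PPINetwork`.

    Rules: a missing third field defaults the weight to 1.0; weights in
    ``(1, 1000]`` are divided by 1000 (STRING combined-score convention);
    negative weights or weights above 1000 are rejected; self-loops are dropped
    (their endpoint is kept as a node); duplicate edges keep the maximum weight.
    """
    graph = nx.Graph()
    duplicates = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FileFormatError(path, lineno, f"expected at least 2 fields, got {len(fields)}")
        u, v = fields[0], fields[1]
        if len(fields) >= 3:
            try:
                weight = float(fields[2])
            except ValueError:
                raise FileFormatError(path, lineno, f"non-numeric edge weight {fields[2]!r}") from None
        else:
            weight = 1.0
        if weight < 0 or weight > 1000:
            raise FileFormatError(path, lineno, f"edge weight {weight} outside [0, 1000]")
        if weight > 1:
            weight /= 1000.0
        graph.add_node(u)
        graph.add_node(v)
        if u == v:
            continue  # self-loop dropped, endpoint retained
        if graph.has_edge(u, v):
            duplicates += 1
            weight = max(weight, graph[u][v]["weight"])
        graph.add_edge(u, v, weight=weight)
    if duplicates:
        logger.info("network %s: %d duplicate edges collapsed (max weight kept)", network_id, duplicates)
    return PPINetwork(network_id=network_id, graph=graph)


def load_similarity_bitscores(path, networks: list[PPINetwork]) -> SimilarityStore:
    """Parse a 3-column ``protein protein bitscore`` file.

    Pairs whose proteins both live in one and the same network are rejected;
    pairs referencing proteins absent from every loaded network are skipped
    with a warning.
    """
    membership: dict[str, set[str]] = {}
    for net in networks:
        for node in net.graph.nodes:
            membership.setdefault(node, set()).add(net.network_id)
    store = SimilarityStore("bitscore")
    skipped = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise FileFormatError(path, lineno, f"expected 3 fields (protein protein score), got {len(fields)}")
        u, v, raw = fields[0], fields[1], fields[2]
        try:
            score = float(raw)
        except ValueError:
            raise FileFormatError(path, lineno, f"non-numeric bit score {raw!r}") from None
        if score < 0:
            raise FileFormatError(path, lineno, f"negative bit score {score}")
        nets_u = membership.get(u)
        nets_v = membership.get(v)
        if not nets_u or not nets_v:
            skipped += 1
            logger.warning("%s:%d: pair (%s, %s) references unknown protein(s); skipped", path, lineno, u, v)
            continue
        if len(nets_u) == 1 and nets_u == nets_v:
            raise FileFormatError(
                path, lineno, f"proteins {u!r} and {v!r} both belong to network {next(iter(nets_u))!r}"
            )
        store.add_pair(u, v, score)
    if skipped:
        logger.info("bit-score file %s: %d pairs skipped (unknown proteins)", path, skipped)
    return store


def load_similarity_cogs(path) -> SimilarityStore:
    """Parse a ``protein group [group ...]`` orthology-membership file."""
    store = SimilarityStore("cog")
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FileFormatError(path, lineno, f"protein {fields[0]!r} has no orthology groups")
        store.add_groups(fields[0], fields[1:])
    return store


def load_annotations(path) -> AnnotationStore:
    """Parse a lenient GO-annotation file.

    Each line is a protein followed by free-text description tokens and GO term
    identifiers in any order.  Terms prefixed ``C:`` / ``P:`` / ``F:`` are routed
    to the matching namespace; bare ``GO:nnnnnnn`` ids go to ``unclassified``.
    """
    store = AnnotationStore()
    for _lineno, line in _data_lines(path):
        fields = line.split()
        protein = fields[0]
        desc_tokens: list[str] = []
        buckets = store.go_terms.setdefault(protein, {ns: [] for ns in GO_NAMESPACES})
        for token in fields[1:]:
            match = _GO_TOKEN_RE.match(token)
            if match is None:
                desc_tokens.append(token)
                continue
            prefix, term = match.groups()
            namespace = _GO_PREFIX_TABLE.get((prefix or "").upper(), "unclassified")
            if term not in buckets[namespace]:
                buckets[namespace].append(term)
        if desc_tokens:
            existing = store.descriptions.get(protein)
            text = " ".join(desc_tokens)
            store.descriptions[protein] = f"{existing} {text}" if existing else text
    return store


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_network_file(network: PPINetwork, path) -> None:
    """Write a network back out as a sorted 3-column edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# network {network.network_id}: weighted edge list\n")
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\t{network.graph[u][v]['weight']:.6f}\n")


def write_bitscore_file(store: SimilarityStore, path) -> None:
    if store.mode != "bitscore":
        raise ValueError("store is not in bitscore mode")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\tprotein\tbit score\n")
        for (u, v), score in sorted(store.pair_scores.items()):
            fh.write(f"{u}\t{v}\t{score:.6f}\n")


def write_cog_file(groups: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\torthology groups\n")
        for protein in sorted(groups):
            fh.write(protein + "\t" + "\t".join(sorted(groups[protein])) + "\n")


def write_annotation_file(store: AnnotationStore, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\tdescription\tGO terms (C:/P:/F: prefixed)\n")
        proteins = sorted(set(store.descriptions) | set(store.go_terms))
        prefix_of = {v: k for k, v in _GO_PREFIX_TABLE.items()}
        for protein in proteins:
            tokens = [protein]
            desc = store.descriptions.get(protein, "")
            if desc:
                tokens.append(desc)
            for namespace in GO_NAMESPACES:
                pre = prefix_of.get(namespace)
                for term in store.terms(protein, namespace):
                    tokens.append(f"{pre}:{term}" if pre else term)
            fh.write("\t".join(tokens) + "\n")


def write_alignment_file(alignment, networks: list[PPINetwork], path) -> None:
    """Write one local alignment as a three-section text file.

    Sections: header (networks, size, density, ISC); one ``>subgraph`` edge-list
    block per network with that network's induced aligned subgraph; a ``>mapping``
    block with one tab-separated row of aligned proteins per alignment row.
    """
    from .core import local_density  # local import avoids a module cycle
    from .postprocess import isc_score

    density = local_density(alignment, networks)
    isc = isc_score(alignment, networks)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gasoline local alignment\n")
        fh.write("networks\t" + "\t".join(alignment.network_ids) + "\n")
        fh.write(f"size\t{len(alignment.rows)}\n")
        fh.write(f"density\t{density:.4f}\n")
        fh.write(f"isc\t{isc:.2f}\n")
        for idx, net in enumerate(networks):
            fh.write(f">subgraph\t{net.network_id}\n")
            column = set(alignment.column(idx))
            induced = sorted(
                tuple(sorted((u, v))) for u, v in net.graph.edges if u in column and v in column
            )
            for u, v in induced:
                fh.write(f"{u}\t{v}\t{net.graph[u][v]['weight']:.6f}\n")
        fh.write(">mapping\n")
        for row in alignment.rows:
            fh.write("\t".join(row) + "\n")


def read_alignment_file(path):
    """Parse a file written by :func:`write_alignment_file` back into an Alignment."""
    from .core import Alignment

    network_ids: tuple[str, ...] | None = None
    rows: list[tuple[str, ...]] = []
    section = "header"
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == ">subgraph":
            section = "subgraph"
            continue
        if fields[0] == ">mapping":
            section = "mapping"
            continue
        if section == "header" and fields[0] == "networks":
            network_ids = tuple(fields[1:])
        elif section == "mapping":
            if network_ids is None or len(fields) != len(network_ids):
                raise FileFormatError(path, lineno, "mapping row does not match the declared networks")
            rows.append(tuple(fields))
    if network_ids is None:
        raise FileFormatError(path, None, "missing 'networks' header line")
    if not rows:
        raise FileFormatError(path, None, "missing mapping section")
    return Alignment(network_ids=network_ids, rows=rows)
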