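"""The three-phase stochastic local-alignment algorithm.

An alignment is an ordered set of *rows*, each row holding exactly one protein per
input network (a one-to-one mapping across networks).  The algorithm runs in three
phases per restart:

1. **bootstrap** — a Gibbs sampler draws a seed row among high-degree candidate
   nodes, resampling one network's member at a time with probability proportional
   to its similarity to the currently fixed members;
2. **extension** — rows are greedily appended, each sampled by a short Gibbs run
   that blends cross-network similarity with weighted connectivity to the already
   aligned subgraphs, and a step is kept only while the growth objective (the
   densest-subgraph degree density, averaged over networks) strictly increases;
3. **refinement** — for a fixed number of iterations the weakest row is removed
   and one replacement row is sampled; the swap is kept only when the
   (density, similarity) objective does not decrease.

All randomness flows through a single :class:`numpy.random.Generator`, so a run is
fully reproducible from ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

from .io_formats import PPINetwork, SimilarityStore

logger = logging.getLogger("gasoline")

__all__ = [
    "GasolineConfig",
    "Alignment",
    "GasolineError",
    "NoSeedFoundError",
    "candidate_seed_nodes",
    "row_similarity",
    "gibbs_sample_seed",
    "local_density",
    "degree_density",
    "extend_alignment",
    "refine_alignment",
    "run_gasoline",
]

#: Additive floor of the Gibbs conditionals, letting the chain escape
#: zero-similarity states.
EPSILON = 1e-6


class GasolineError(RuntimeError):
    """Base class for alignment-pipeline failures."""


class NoSeedFoundError(GasolineError):
    """No network has a usable seed candidate (degree >= sigma)."""


@dataclass
class GasolineConfig:
    """The six aligner parameters plus reproducibility knobs.

    iter_seed / iter_extend
        Gibbs iterations in the bootstrap phase and in each extension step.
        200 iterations are sufficient for reliable sampling up to ~25 networks.
    sigma
        Minimum degree of seed candidates.  High sigma is faster but less
        accurate; 1–2 is recommended for sparse networks.
    overlap
        Maximum fraction of shared nodes for two alignments to count as
        distinct; of an overlapping pair the smaller one is discarded.
    refine
        Refinement iterations per alignment; 10 trades speed against accuracy well.
    min_complex_size
        Minimum number of rows of a reported conserved complex.
    rng_seed
        Seed of the single random stream driving all three phases.
    restarts
        Independent seed→extend→refine attempts.  ``None`` picks the number of
        seed candidates of the smallest network, capped at 100.
    """

    iter_seed: int = 200
    iter_extend: int = 200
    sigma: int = 7
    overlap: float = 0.5
    refine: int = 10
    min_complex_size: int = 5
    rng_seed: int = 0
    restarts: Optional[int] = None

    def __post_init__(self):
        if self.iter_seed < 0 or self.iter_extend < 0 or self.refine < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.min_complex_size < 1:
            raise ValueError("min_complex_size must be at least 1")
        if self.restarts is not None and self.restarts < 1:
            raise ValueError("restarts must be positive")


@dataclass
class Alignment:
    """An ordered list of alignment rows over a fixed tuple of networks.

    ``density_trace`` records the extension objective (degree density) after the
    seed and after each accepted extension step — strictly increasing by
    construction.  ``objective_trace`` records the (density, similarity)
    refinement objective per iteration — non-decreasing by construction.
    ``density`` and ``isc`` are filled in by :func:`run_gasoline` for reporting.
    """

    network_ids: tuple[str, ...]
    rows: list[tuple[str, ...]]
    density_trace: list[float] = field(default_factory=list)
    objective_trace: list[tuple[float, float]] = field(default_factory=list)
    density: Optional[float] = None
    isc: Optional[float] = None

    def column(self, index: int) -> list[str]:
        """The aligned nodes of network *index*, in row order."""
        return [row[index] for row in self.rows]

    @property
    def size(self) -> int:
        return len(self.rows)

    def node_set(self) -> set[tuple[str, str]]:
        """All aligned nodes as (network_id, protein) pairs."""
        return {
            (net, row[i])
            for row in self.rows
            for i, net in enumerate(self.network_ids)
        }

    def is_column_injective(self) -> bool:
        return all(
            len(set(self.column(i))) == len(self.rows)
            for i in range(len(self.network_ids))
        )


def _check_networks(alignment: Alignment, networks: Sequence[PPINetwork]) -> None:
    if tuple(n.network_id for n in networks) != alignment.network_ids:
        raise ValueError("networks do not match the alignment's network order")


# ---------------------------------------------------------------------------
# Bootstrap phase
# ---------------------------------------------------------------------------


def candidate_seed_nodes(network: PPINetwork, sigma: int) -> set[str]:
    """Nodes eligible as seed members: degree at least *sigma*."""
    return {node for node, deg in network.graph.degree if deg >= sigma}


def row_similarity(row: Sequence[str], sim: SimilarityStore) -> float:
    """Total cross-network similarity of a row: sum over all network pairs."""
    score = sim.score
    return sum(score(u, v) for u, v in combinations(row, 2))


def _categorical(rng: np.random.Generator, weights: np.ndarray) -> int:
    """Draw an index with probability proportional to *weights* (all > 0)."""
    cumulative = np.cumsum(weights)
    return int(np.searchsorted(cumulative, rng.random() * cumulative[-1], side="right"))


class _ScoreVectors:
    """Memoised similarity vectors: score of every candidate of one network
    against a fixed partner node.  Gibbs sweeps revisit the same partners many
    times, so caching turns the conditional into a few vector adds."""

    def __init__(self, candidates: list[list[str]], sim: SimilarityStore):
        self._candidates = candidates
        self._score = sim.score
        self._cache: list[dict[str, np.ndarray]] = [{} for _ in candidates]

    def against(self, network_index: int, partner: str) -> np.ndarray:
        cache = self._cache[network_index]
        vec = cache.get(partner)
        if vec is None:
            score = self._score
            vec = np.array([score(x, partner) for x in self._candidates[network_index]])
            cache[partner] = vec
        return vec


def gibbs_sample_seed(
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
    config: GasolineConfig,
    rng: np.random.Generator,
) -> Optional[tuple[str, ...]]:
    """Sample one seed row by Gibbs sampling over the per-network candidates.

    The row is initialised uniformly; for ``iter_seed`` iterations one network
    (round-robin) has its member resampled with probability proportional to
    ``EPSILON +`` its summed similarity to the other fixed members.  The
    best-scoring row visited (by :func:`row_similarity`) is returned, or ``None``
    when some network has no candidate of degree >= sigma.
    """
    candidates = [sorted(candidate_seed_nodes(net, config.sigma)) for net in networks]
    if any(not cand for cand in candidates):
        return None
    n_networks = len(networks)
    row = [cand[rng.integers(len(cand))] for cand in candidates]
    vectors = _ScoreVectors(candidates, sim)
    best_row = tuple(row)
    best_score = row_similarity(best_row, sim)
    for step in range(config.iter_seed):
        i = step % n_networks
        weights = np.full(len(candidates[i]), EPSILON)
        for j in range(n_networks):
            if j != i:
                weights = weights + vectors.against(i, row[j])
        row[i] = candidates[i][_categorical(rng, weights)]
        score = row_similarity(row, sim)
        if score > best_score:
            best_row, best_score = tuple(row), score
    return best_row


# ---------------------------------------------------------------------------
# Density objectives
# ---------------------------------------------------------------------------


def _induced_weight_sums(alignment: Alignment, networks: Sequence[PPINetwork]) -> list[float]:
    """Summed induced edge weights per network, iterated in sorted node order so
    floating-point accumulation is deterministic for a given row set."""
    sums = []
    for index, net in enumerate(networks):
        adj = net.graph.adj
        column = sorted(set(alignment.column(index)))
        total = 0.0
        for a, b in combinations(column, 2):
            data = adj[a].get(b) if a in adj else None
            if data is not None:
                total += data["weight"]
        sums.append(total)
    return sums


def local_density(alignment: Alignment, networks: Sequence[PPINetwork]) -> float:
    """Pairwise-normalised weighted density, averaged over networks.

    For each network: sum of induced edge weights divided by C(k, 2), with k the
    number of rows; 0 by convention below 2 rows.  Bounded in [0, 1]; this is the
    density reported in output headers.
    """
    k = len(alignment.rows)
    if k < 2:
        return 0.0
    sums = _induced_weight_sums(alignment, networks)
    pairs = comb(k, 2)
    return sum(s / pairs for s in sums) / len(networks)


def degree_density(alignment: Alignment, networks: Sequence[PPINetwork]) -> float:
    """Degree-normalised weighted density, averaged over networks.

    For each network: sum of induced edge weights divided by k (the
    densest-subgraph objective of Goldberg/Charikar).  Unlike the pairwise
    normalisation, this quantity grows strictly along a quasi-clique, which makes
    it the extension phase's acceptance objective.
    """
    k = len(alignment.rows)
    if k < 1:
        return 0.0
    sums = _induced_weight_sums(alignment, networks)
    return sum(s / k for s in sums) / len(networks)


# ---------------------------------------------------------------------------
# Extension phase
# ---------------------------------------------------------------------------


def _sample_extension_row(
    alignment: Alignment,
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
    iterations: int,
    rng: np.random.Generator,
) -> Optional[tuple[str, ...]]:
    """Gibbs-sample one new row adjacent to the current alignment.

    Candidates per network are the neighbours of that network's aligned column,
    excluding nodes already in the column (which preserves column injectivity).
    The conditional weight of a candidate blends, with equal weight, its
    similarity to the other tentative members and its summed edge weight into
    the aligned column.  Returns the best row visited by that blended score, or
    ``None`` when any network has no candidates.
    """
    n_networks = len(networks)
    candidates: list[list[str]] = []
    connectivity: list[np.ndarray] = []
    for index, net in enumerate(networks):
        adj = net.graph.adj
        used = set(alignment.column(index))
        cand = sorted({nbr for u in used for nbr in adj[u]} - used)
        if not cand:
            return None
        conn = np.array(
            [sum(data["weight"] for nbr, data in adj[c].items() if nbr in used) for c in cand]
        )
        candidates.append(cand)
        connectivity.append(conn)
    conn_of = [dict(zip(cand, conn)) for cand, conn in zip(candidates, connectivity)]
    vectors = _ScoreVectors(candidates, sim)

    def blended(row: Sequence[str]) -> float:
        return row_similarity(row, sim) + sum(conn_of[i][row[i]] for i in range(n_networks))

    row = [cand[rng.integers(len(cand))] for cand in candidates]
    best_row = tuple(row)
    best_score = blended(best_row)
    for step in range(iterations):
        i = step % n_networks
        weights = connectivity[i] + EPSILON
        for j in range(n_networks):
            if j != i:
                weights = weights + vectors.against(i, row[j])
        row[i] = candidates[i][_categorical(rng, weights)]
        score = blended(row)
        if score > best_score:
            best_row, best_score = tuple(row), score
    return best_row


def extend_alignment(
    alignment: Alignment,
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
    config: GasolineConfig,
    rng: np.random.Generator,
) -> Alignment:
    """Greedily append rows while the degree-density objective strictly increases.

    Each step Gibbs-samples a candidate row, tentatively appends it and keeps it
    iff the objective strictly increased; the first non-improving row is reverted
    and extension stops.  Returns a new alignment carrying the strictly
    increasing ``density_trace``.
    """
    _check_networks(alignment, networks)
    rows = list(alignment.rows)
    current = Alignment(alignment.network_ids, rows)
    objective = degree_density(current, networks)
    trace = [objective]
    while True:
        new_row = _sample_extension_row(current, networks, sim, config.iter_extend, rng)
        if new_row is None:
            break
        rows.append(new_row)
        new_objective = degree_density(current, networks)
        if new_objective > objective:
            objective = new_objective
            trace.append(new_objective)
        else:
            rows.pop()
            break
    logger.debug(
        "extension: %d rows accepted, final objective %.4f", len(rows) - len(alignment.rows), objective
    )
    return Alignment(
        alignment.network_ids,
        rows,
        density_trace=trace,
        objective_trace=list(alignment.objective_trace),
    )


# ---------------------------------------------------------------------------
# Refinement phase
# ---------------------------------------------------------------------------


def _row_contribution(
    alignment: Alignment, networks: Sequence[PPINetwork], sim: SimilarityStore, row_index: int
) -> float:
    """A row's stake in the alignment: its similarity plus its summed edge
    weights into the rest of each column."""
    row = alignment.rows[row_index]
    total = row_similarity(row, sim)
    for i, net in enumerate(networks):
        adj = net.graph.adj
        others = {r[i] for k, r in enumerate(alignment.rows) if k != row_index}
        total += sum(data["weight"] for nbr, data in adj[row[i]].items() if nbr in others)
    return total


def _refinement_objective(
    rows: list[tuple[str, ...]],
    network_ids: tuple[str, ...],
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
) -> tuple[float, float]:
    working = Alignment(network_ids, rows)
    return (
        degree_density(working, networks),
        sum(row_similarity(row, sim) for row in rows),
    )


def refine_alignment(
    alignment: Alignment,
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
    config: GasolineConfig,
    rng: np.random.Generator,
) -> Alignment:
    """Iteratively swap out the weakest row for a freshly sampled one.

    For ``refine`` iterations the row with the lowest contribution is removed and
    one extension attempt proposes a replacement; the swap is accepted iff the
    (degree density, total similarity) objective does not decrease
    lexicographically.  The recorded ``objective_trace`` is non-decreasing.
    """
    _check_networks(alignment, networks)
    rows = list(alignment.rows)
    if config.refine == 0 or len(rows) < 2:
        return replace(alignment, rows=rows, objective_trace=[
            _refinement_objective(rows, alignment.network_ids, networks, sim)
        ])
    objective = _refinement_objective(rows, alignment.network_ids, networks, sim)
    trace = [objective]
    for _iteration in range(config.refine):
        working = Alignment(alignment.network_ids, rows)
        contributions = [
            _row_contribution(working, networks, sim, k) for k in range(len(rows))
        ]
        worst = min(range(len(rows)), key=lambda k: (contributions[k], k))
        trial = rows[:worst] + rows[worst + 1 :]
        replacement = _sample_extension_row(
            Alignment(alignment.network_ids, trial), networks, sim, config.iter_extend, rng
        )
        if replacement is not None:
            trial = trial + [replacement]
        new_objective = _refinement_objective(trial, alignment.network_ids, networks, sim)
        if new_objective[0] > objective[0] or (
            new_objective[0] == objective[0] and new_objective[1] >= objective[1]
        ):
            rows, objective = trial, new_objective
        trace.append(objective)
    return Alignment(
        alignment.network_ids,
        rows,
        density_trace=list(alignment.density_trace),
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_gasoline(
    networks: Sequence[PPINetwork],
    sim: SimilarityStore,
    config: GasolineConfig,
) -> list[Alignment]:
    """Run seed → extend → refine for ``restarts`` attempts and post-process.

    Post-processing enforces the minimum complex size, discards the smaller of
    any two alignments sharing more than an ``overlap`` fraction of nodes, and
    sorts the survivors by size (descending) then ISC (descending).  The result
    is deterministic given the inputs and ``rng_seed``.
    """
    from .postprocess import filter_min_size, filter_overlap, isc_score

    if len(networks) < 2:
        raise GasolineError("at least two networks are required for an alignment")
    ids = tuple(n.network_id for n in networks)
    if len(set(ids)) != len(ids):
        raise GasolineError(f"network ids are not unique: {ids}")
    rng = np.random.default_rng(config.rng_seed)

    restarts = config.restarts
    if restarts is None:
        smallest = min(networks, key=lambda n: n.graph.number_of_nodes())
        restarts = min(100, max(1, len(candidate_seed_nodes(smallest, config.sigma))))

    raw: list[Alignment] = []
    for attempt in range(restarts):
        seed_row = gibbs_sample_seed(networks, sim, config, rng)
        if seed_row is None:
            raise NoSeedFoundError(
                f"no seed candidates with degree >= {config.sigma} in some network; lower sigma"
            )
        alignment = Alignment(ids, [seed_row])
        logger.debug(
            "restart %d: seed %s (similarity %.2f)", attempt, seed_row, row_similarity(seed_row, sim)
        )
        alignment = extend_alignment(alignment, networks, sim, config, rng)
        alignment = refine_alignment(alignment, networks, sim, config, rng)
        assert alignment.is_column_injective()
        raw.append(alignment)
        logger.info(
            "restart %d: %d rows, objective %.4f",
            attempt,
            alignment.size,
            alignment.objective_trace[-1][0] if alignment.objective_trace else 0.0,
        )

    kept = filter_min_size(raw, config.min_complex_size)
    kept = filter_overlap(kept, config.overlap)
    for alignment in kept:
        alignment.density = local_density(alignment, networks)
        alignment.isc = isc_score(alignment, networks)
    kept.sort(key=lambda a: (-a.size, -(a.isc or 0.0)))
    logger.info("pipeline: %d restarts -> %d conserved complexes", restarts, len(kept))
    return kept
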