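# Methods

## Model and assumptions

The aligner treats each species' PPI network as an undirected simple graph with
edge weights in [0, 1] interpreted as interaction probabilities (STRING-style
combined scores in (1, 1000] are rescaled by 1/1000 at load time; duplicate
edges keep the maximum weight; self-loops are dropped). Cross-species protein
similarity is either an explicit pairwise bit-score table (unlisted pairs score
0) or orthology-group membership, where the implied score of a cross-network
pair is its number of shared COG/KOG/NOG groups. GO annotations are purely
decorative: they are attached to exported alignment graphs and are never read
by any scoring or sampling step, which the test suite asserts by byte-comparing
runs with and without an annotation file.

A local alignment is an ordered list of rows, one protein per network per row,
injective within each network's column. The method assumes conserved complexes
appear as relatively dense, mutually similar subgraphs in every network; it
produces a strict one-to-one mapping and does not model paralog expansions
(one-to-many mappings), directed interactions, or multi-edges.

## The three phases

**Bootstrap.** Seed candidates are the nodes of degree ≥ σ. The Gibbs sampler
initialises a row uniformly and, for `iter_seed` iterations, resamples one
network's member (round-robin — cyclic scans are standard Gibbs practice and
deterministic in order) with probability proportional to ε + the summed
similarity to the other fixed members, ε = 10⁻⁶ being an additive floor that
lets the chain leave zero-similarity states. The sampler returns the
best-scoring row visited rather than the final state: the target is the optimal
seed, not a posterior sample.

**Extension.** Per-network candidates are the neighbours of the aligned column
minus the column itself (which preserves injectivity by construction). The
conditional weight of a candidate blends, with equal weight and both raw, its
similarity to the other tentative members and its summed edge weight into the
aligned column; the best row visited is tentatively appended. The step is kept
iff the growth objective strictly increased, otherwise the row is reverted and
extension stops.

The growth objective is the *degree density* — mean over networks of
(induced edge-weight sum)/k for k rows, the Goldberg/Charikar densest-subgraph
objective — not the pairwise-normalised density Σw/C(k,2) reported for finished
complexes. The choice is deliberate: the pairwise normalisation is constant
along a homogeneous quasi-clique (a weight-w clique has density w at every
size), so no strict-improvement rule on it could ever grow a conserved complex
past two rows, while the degree density grows strictly along quasi-cliques
(for a weight-w clique it is w·(k−1)/2) and still falls when a sparsely
connected row is appended. A side effect is a clean stopping rule: a new row is
accepted exactly when its edge mass into the alignment exceeds the current mean
per-row mass, so extension stops at the boundary of a planted complex instead
of bleeding into the sparse background.

**Refinement.** For `refine` iterations the row with the lowest contribution
(its similarity plus its edge weights into the rest of each column; ties broken
by row index) is removed and one replacement row is sampled by the extension
machinery. The swap is accepted iff the pair (degree density, total row
similarity) does not decrease lexicographically; total similarity breaks exact
density ties, which occur when the sampler re-proposes the removed row.

**Restarts and post-processing.** The number of independent
seed→extend→refine attempts defaults to the number of seed candidates in the
smallest network, capped at 100 — enough for restarts to cover the distinct
high-similarity seeds while bounding cost. Nodes may be reused across restarts;
duplicates and near-duplicates are resolved afterwards by the overlap filter.
Filtering order is min-size first, then overlap, so a small alignment can never
eliminate a large one before being dropped itself. The overlap fraction
normalises shared (network, protein) nodes by the smaller alignment's node
count (fewer rows; ties by node count, then discovery order), so a contained
sub-alignment always overlaps fully and is discarded.

## Parameters

| name | default | meaning |
|---|---|---|
| iter_seed | 200 | Gibbs iterations, bootstrap phase (enough up to ~25 networks) |
| iter_extend | 200 | Gibbs iterations per extension step |
| sigma | 7 | minimum seed-candidate degree; 1–2 recommended for sparse networks |
| overlap | 0.5 | maximum shared-node fraction for two alignments to be distinct |
| refine | 10 | refinement iterations (speed/accuracy trade-off) |
| min_complex_size | 5 | minimum rows of a reported complex |
| rng_seed | 0 | seed of the single numpy Generator driving all phases |
| restarts | auto | seed attempts; default min(candidates of smallest network, 100) |

## Numerical and determinism choices

All stochastic draws come from one `numpy.random.Generator`, consumed
sequentially across restarts, so identical inputs, configuration and seed give
byte-identical output files. Induced edge-weight sums iterate nodes in sorted
order, making floating-point accumulation order-independent of discovery
history; exact float equality is therefore meaningful in the refinement
tie-break. Candidate lists are sorted before sampling. Categorical draws use a
cumulative-sum inversion of a single uniform variate. Degenerate inputs:
alignments below two rows have density 0 and ISC 0 by convention; an ISC
network pair with two empty induced edge sets counts as fully conserved (Dice
limit 1); extension returns its input unchanged when any network has no unused
neighbours; a network with no degree-≥σ node makes the run fail with an
explicit "no seed" error rather than silently returning nothing.

The ISC is the unweighted Dice coefficient of induced edge sets under the row
mapping, averaged over network pairs and scaled to a percentage: symmetric,
bounded, and exactly 100 iff every network pair is edge-identical under the
mapping. Intra-edge colour classes use fixed tertiles of the [0, 1] weight
range (green < 1/3 ≤ yellow < 2/3 ≤ red) rather than data-driven quantiles, so
colours are comparable across alignments and runs.

## Synthetic study conditions

The fixture generator plants conserved complexes into Erdős–Rényi backgrounds:
per network, 60 nodes wired with probability 0.05 and light weights U(0.1, 0.5);
each planted complex designates m = 6 of those nodes, wired with probability
0.9 and heavy weights U(0.7, 1.0), with counterpart nodes named so the ground
truth is self-describing. Counterpart pairs score bit score 200; decoy pairs
(one per background node per network pair, drawn uniformly over the node sets)
score U(0, 20). The light/heavy weight bands separate the low/high colour
classes and make density-driven extension well-posed; plantings are detectable
by construction (complex denser than background, counterpart similarity above
every decoy), which the spec validator enforces. Nodes left isolated by the
random wiring are dropped so generated networks honour the edge-list invariant.

What the generator does *not* emulate: scale-free or duplication–divergence
degree structure, correlated noise between similarity and topology, paralog
families, or missing/spurious interactions beyond independent random wiring.
Passing the recovery tests therefore shows the machinery finds dense,
mutually similar subgraphs under honest noise — not that it handles the full
messiness of experimental interactomes.

Problem sizes used by the default test suite and the acceptance script —
20 pipeline runs on the 3×60-node two-complex fixture, 100 five-candidate
seed-optimality instances, 200-instance oracle comparisons for ISC and the
overlap filter — were chosen to make the stochastic assertions stable across
seeds while keeping a full run in the order of a minute.

## Known limitations

* One-to-one mapping only; a conserved complex with unequal sizes across
  species is recovered at the size of its smallest member at best.
* Extension adds exactly one node per network per step, so a complex absent
  from one network cannot be aligned among the remaining networks.
* The degree-density stopping rule is scale-sensitive: a very heavy core can
  absorb a moderately connected periphery node whose edge mass exceeds the
  current per-row mean.
* Runtime grows with restarts × (iter_seed + steps × iter_extend) and with the
  candidate-neighbourhood sizes, i.e. with network density; very dense networks
  should raise σ or cap restarts.
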