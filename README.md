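# gasoline-align

Multiple **local alignment of protein–protein interaction (PPI) networks**:
find sets of proteins — one per species — whose interaction patterns are
conserved across two or more networks, i.e. candidate conserved protein
complexes. The package implements the GASOLINE approach (Greedy And Stochastic
algorithm for Optimal Local alignment of Interaction NEtworks) as a library and
command-line tool with plain-text inputs and outputs.

## Who this is for

Computational biologists comparing PPI networks of evolutionarily distant
species: local alignment surfaces conserved complexes and pathways that
sequence comparison alone cannot, and supports transferring functional
annotation between species.

## The method

Each input network *G<sub>i</sub> = (V<sub>i</sub>, E<sub>i</sub>, w)* is an
undirected graph whose edge weights *w(u,v) ∈ [0,1]* are interaction
probabilities. A cross-network similarity *s(u,v)* (BLAST bit scores, or shared
COG/KOG/NOG orthology groups) links proteins of different species. An
**alignment** is an ordered set of rows, each row **r** = (r₁, …, r_N) holding
one protein per network, with all rows distinct within every network's column
(a one-to-one mapping). Three phases per restart:

1. **Bootstrap** — a Gibbs sampler over the per-network candidates (nodes of
   degree ≥ σ) resamples one coordinate at a time with probability ∝
   ε + Σ_{j≠i} s(x, r_j), and returns the best row visited by total similarity
   Σ_{i<j} s(r_i, r_j): the seed.
2. **Extension** — rows adjacent to the aligned subgraphs are Gibbs-sampled
   with conditional weight ∝ ε + similarity + weighted connectivity to the
   aligned column; a row is kept only while the growth objective — the
   densest-subgraph degree density, mean over networks of
   Σ<sub>induced</sub> w / k for k rows — **strictly increases**.
3. **Refinement** — for a fixed number of iterations the lowest-contributing
   row is removed and a replacement sampled; the swap is kept iff
   (density, total similarity) does not decrease.

Alignments below the minimum complex size are dropped; of two alignments
sharing more than an `overlap` fraction of nodes the smaller is discarded.
Each reported complex carries its weighted density (Σw / C(k,2), averaged over
networks) and its **ISC** (Index of Structural Conservation): the mean over
network pairs of the Dice coefficient 2·|conserved edges| / (|E_i| + |E_j|)
between induced subgraphs under the row mapping, as a percentage.

Parameter defaults: IterSeed = 200, IterExtend = 200, Sigma = 7 (use 1–2 for
sparse networks), Overlap = 0.5, Refine = 10, MinComplexSize = 5.

## Worked example

The built-in demo generates three synthetic 60-node networks with two planted
size-6 conserved complexes plus a matching bit-score file, runs the full
pipeline (σ = 2 for the sparse backgrounds), and scores recovery of the
planted rows:

```text
$ gasoline demo --out demo_run --seed 1
2 conserved complex(es) found
  alignment_001.txt: size=6 ISC=90.21% density=0.7992
  alignment_002.txt: size=6 ISC=87.18% density=0.7274
planted-row recall = 1.000
planted-row precision = 1.000
```

Both planted complexes are recovered exactly (recall and precision 1.0): each
reported alignment has 6 rows, a weighted density near 0.8 (the complexes were
planted with edge probability 0.9 and weights in [0.7, 1.0]), and ISC near 90%
— the complexes were wired independently per network, so roughly 0.9² of the
possible edges are conserved in both members of a network pair. Each alignment
is written as a text file (header, per-network induced subgraph edge lists, and
the row mapping) plus a GraphML alignment graph whose solid intra-edges are
colour-classed green/yellow/red by weight and whose dashed inter-edges join the
mapped proteins of each row.

Aligning your own data:

```sh
gasoline align --net worm.txt --net fly.txt --net yeast.txt \
    --sim bitscores.tsv --sim-format bitscore \
    --go annotations.txt --sigma 2 --seed 7 --out results/
```

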