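# Methods

## The multilayer graph model

A multilayer network is a node set plus an undirected attributed edge
list of tuples `(u, v, l)`: `l` names the layer an edge lies in, with one
dedicated identifier for interlayer edges (by convention the largest
identifier present, e.g. layers 1 and 2 with interlayer 3).  Intralayer
edges `E_a` and interlayer edges `E_b` partition the edge set.  Node
identifiers are opaque strings and global: the same identifier in two
layers denotes one entity, which is what makes the flat representation —
one graph with edges typed by their originating layer — losslessly
equivalent (`from_flat(to_flat(net)) == net`).  Self-loops and parallel
edges are excluded; duplicate and reversed-duplicate input lines are
collapsed with a warning.  Neighbourhoods `Γ(u)` always pool all layers,
intralayer and interlayer: a node is characterised by the whole set of
its interactions.

## Synthetic benchmark generator

Each layer grows by preferential attachment: `n` nodes, each new node
attaching with `m` edges to targets drawn proportionally to degree.
After each attachment, with probability `p` one extra edge is added
between two randomly chosen existing non-adjacent nodes, and with
probability `q` one edge is removed, drawn uniformly from the edges whose
endpoints both have degree ≥ 2 (so no node is ever isolated).  The
`p`-event fires before the `q`-event; the growth process fixes no order,
so this is a convention, applied identically under a fixed seed.  With
`p = q = 0` the process is plain Barabási–Albert and a layer has exactly
`m(n − m)` edges.

Layers get disjoint name prefixes (`l1_`, `l2_`); interlayer edges are
sampled uniformly without replacement over cross-layer node pairs until
`|E_b| = round(f/(1−f) · |E_a|)`, making interlayer edges the fraction
`f` (default 0.20) of the final total edge count — "total" is read as
including both edge classes.  The ground-truth mapping of a generated
benchmark is the identity on node identifiers.

Noisy counterparts remove `floor(fraction · |E_M|)` edges sampled
uniformly over the pooled intralayer+interlayer set, re-sampling any
candidate whose removal would isolate an endpoint; the node set is
preserved, which keeps the identity truth mapping total.  Similarity
matrices are noised by replacing a uniformly chosen `floor(fraction ·
size)` subset of entries with draws from the empirical distribution of
the untouched entries (range-preserving); Gaussian jitter is available
behind a flag.  Rounding uses floor for both noise operations — no
rounding rule is canonical, so one was fixed.

What the generator does *not* emulate: heterogeneous node types with
per-layer semantics, degree correlations between layers, and the scale of
real curated networks (thousands of nodes, most edges interlayer).
Passing benchmarks therefore demonstrate recovery of topology under
controlled degradation, not performance on any particular real dataset.

## Embeddings

Walks run on the flat graph, ignoring edge types — interlayer edges are
treated as independent edges, traversed like any other.  The walk is the
second-order biased walk: stepping from `cur` with predecessor `prev`, a
neighbour `x` is weighted `1/return_param` if `x = prev`, `1` if `x` is
adjacent to `prev`, else `1/inout_param`; both parameters default to 1,
which reduces to the uniform first-order walk.  Every node starts
`num_walks` walks of exactly `walk_length` nodes, so the corpus covers
every non-isolated node by construction; isolated nodes are an error.

Training is skip-gram with negative sampling, implemented as a
single-threaded compiled kernel: for each (center, context) pair within
the window, one positive update and `negative = 5` draws from the
unigram^0.75 noise distribution; learning rate decays linearly from 0.025
to 0.0001 over all token positions; the window is fixed (not
sub-sampled).  Default hyperparameters follow common node2vec practice —
`N = 128` dimensions, 10 walks × 80 nodes, window 5, 5 epochs — and are
all exposed.

Two reproducibility choices matter scientifically:

* **Determinism** — walks, negative sampling and initialisation all
  derive from the configured seed, and training is single-threaded, so a
  given (graph, config) pair yields a bit-identical embedding matrix.
* **Per-identifier initialisation** — a node's input vector is
  initialised from a stable hash of its identifier combined with the
  seed.  Two networks sharing node identifiers are therefore embedded in
  *comparable* spaces: identical networks produce identical vectors
  (cosine 1 on the diagonal), and mildly perturbed networks produce
  mildly divergent vectors.  Cross-network cosine similarity is
  meaningful because of this anchoring; without it, independently trained
  embedding spaces would be arbitrary rotations of each other.

"The mean of a node's projection weight vectors" is read as the node's
embedding vector itself (for a single node there is one vector); an
optional neighbourhood-mean query vector is provided separately.

## Alignment

The similarity matrix holds `cos(x_v, y_u)` for all source × target
pairs, rows the smaller network (inputs are swapped and the output
inverted if needed).  The greedy pre-mapping scans candidate pairs in
globally descending similarity — a pair is accepted iff both endpoints
are unmatched — with ties broken lexicographically by (source, target)
label for determinism.  This is deliberately *not* the Hungarian optimal
assignment; a test asserts the distinction on a crafted instance.

Refinement: the Jaccard coefficient of a candidate pair translates the
source node's neighbours into target space through the current mapping
(unmapped neighbours count toward the union only) and compares with the
target node's neighbours.  Pairs with `Jc = 1` are frozen as final.  The
remaining pairs are revisited in ascending-`Jc` order; for each, the best
swap partner among the other open pairs is chosen by the swap's *global*
effect on total `Jc` — the two swapped pairs plus every pair whose
translated neighbourhood involves them — and the swap is accepted only
when that total strictly increases and the total mapped similarity does
not decrease by more than a tolerance (default `1e-9`, configurable;
loosening it lets the refinement trade similarity for overlap more
aggressively).  Iteration stops when a full pass accepts no swap, when
all pairs reach `Jc = 1`, or when the budget — `ceil(0.5 · |pre|)`
*accepted* swaps by default — is exhausted; the stop reason and swap
count are reported.  Evaluating the swap globally is what guarantees the
monotonicity invariant (total `Jc` never decreases), which a
two-pair-local rule would not.

## Evaluation conventions

* **NC** = correctly mapped pairs / truth size; the **alignment score**
  is NC min–max-normalised over one benchmark run (all 60 NC values of a
  full run form the population; an all-equal population is returned
  unscaled).  Because the 0%-noise self-alignment attains the maximum NC,
  its score is 1 by construction of the scaling.
* **Confusion counts**: TP = correct pair, FP = contradicted pair, FN =
  missed truth pair; a forced total one-to-one alignment predicts no
  negatives, so TN = 0 at that operating point (FP = FN follows).  TN
  becomes meaningful only under the ROC threshold sweep.
* **ROC/AUC**: thresholds sweep the per-pair similarity scores
  descending; ties advance together; AUC is the trapezoid area, which
  equals the Mann–Whitney rank statistic (tested against it).
* **F1** aggregates: mean, max, and the noise-level-normalised variant
  (min–max within each noise group, then averaged).
* **ANOVA from summaries** uses `SS_between = Σ n_i(m_i − m̄)²`,
  `SS_within = Σ (n_i−1) s_i²` with sample SDs (n−1); this convention is
  pinned by the fact that it reproduces a published residual SS to five
  decimals.  Recomputing an F-ratio from summaries printed to five
  decimals carries their rounding: agreement with a raw-data F is limited
  to ~1e-3 by error propagation, which is the tolerance the tests use.
* **McNemar** uses `chi2 = max(|b−c|−1, 0)² / (b+c)` with the two-tailed
  p from chi-square(1); at `b = c` the corrected statistic is 0 and
  p = 1.  `b + c = 0` is an explicit error.

## Benchmark problem sizes

The full study conditions are 10 networks (5 per generator parameter set
`(n=100, m=2, p=0.5, q=0.4)` and `(n=100, m=2, p=0.3, q=0.7)`, 2 layers,
20% interlayer), each aligned with itself and with 5–25% noisy copies —
60 alignments per run.  The acceptance script runs these conditions over
3 seeds with a benchmark embedding configuration of 64 dimensions, 10
walks × 40 nodes and 3 epochs, which preserves the score profile of the
full node2vec defaults at a fraction of the training cost; the test
suite's replication test scales to 2 networks per parameter set.  One
embedding is trained per network per run (the source embedding is shared
across a base network's six alignments, which is exact because embedding
is deterministic per graph and seed).

## Known limitations

* Embedding quality (hence NC under noise) depends on hyperparameters
  that have no canonical values; the benchmark tolerances are
  correspondingly wide and stochastic results are averaged over seeds.
* The refinement is a local search: it fixes pairwise crossings but
  cannot realise improvements that require 3-cycles of reassignment.
* The similarity-tolerance default is conservative (swaps must be
  essentially similarity-neutral); alignments dominated by neighbourhood
  structure rather than embedding similarity may benefit from loosening
  it.
* Directed, weighted and attributed edges are out of scope, as are
  many-to-many (local) alignments and simultaneous alignment of more
  than two networks.
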