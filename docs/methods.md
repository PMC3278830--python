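# Methods

## The model

Classical functional enrichment treats a network as a bag of genes: given a
universe *U*, an interesting collection *C* ⊆ *U*, and a function *f*
annotating *U_f* ⊆ *U* genes (of which *C_f* = *C* ∩ *U_f* are interesting),
the one-sided Fisher's exact test asks how likely a uniform draw of
*u_f* = |*U_f*| genes is to contain at least *c_f* = |*C_f*| interesting
ones.  That test is blind to whether the annotated genes actually interact.

`netenrich` evaluates enrichment of *f* in a network.  The inputs are a
universal network *G* = (*U*, *I*) and an interesting network
*H* = (*C*, *J*) with *C* ⊆ *U* and *J* ⊆ *I* (*H* need not be the induced
subgraph: edges of *I* between nodes of *C* may legitimately be missing from
*J*).  Let *H_f* be the subgraph of *H* induced by *U_f* ∩ *C*.  Its
connectivity is summarized by **cs(H_f)**: the non-increasing sequence of
its connected-component sizes.  Two sequences are compared by zero-padding
the shorter one and deciding at the first index where they differ; this is a
total order whose minimum, for a fixed node count, is the all-singletons
sequence.  The null distribution of cs under subset sampling has no known
closed form, so significance is estimated by permutation:

* **Function randomization** draws *X* of size *u_f* uniformly without
  replacement from *U* and reports the fraction of draws with
  cs(H_X) ≥ cs(H_f), where *H_X* is the subgraph of *H* induced by
  *X* ∩ *C*.  If *G* and *H* are stripped of all edges this is exactly the
  Monte-Carlo version of the one-sided Fisher test — the method is a strict
  generalization.
* **Structure randomization** rewires *G* by double edge swaps that preserve
  every node's degree (two distinct edges are picked uniformly, one of the
  two endpoint exchanges is picked uniformly, and the exchange is rejected
  if it would create a self-loop or duplicate an existing edge).  Each of
  the `iterations` rewired networks *G′* induces *H′_f* on *C* ∩ *U_f*, and
  the p-value is the fraction of rewirings with cs(H′_f) ≥ cs(H_f).  The
  observed cs(H_f) always comes from the true *H*; the rewired statistic is
  induced in *G′* — this asymmetry is deliberate and matters only when *H*
  is not induced.

A function must look connected under **both** nulls, so the combined
p-value is the maximum of the two.  The analytic Fisher tail is always
reported alongside as a baseline; in whole-network mode (*H* = *G*) it is 1
for every term while the permutation p-values remain informative.

The **merge score** s(f) = log10(p_r / p_a) compares two runs that share
the universal network and seed: p_a with an edge set included in *H* and
p_r with it removed (edges carrying independent evidence can be kept).
Positive scores mean the edge set improved the function's coherence.  Exact
zeros are floored at 1/iterations before the ratio — the only place any
flooring is applied; everywhere else a reported 0 means "below the grid
resolution 1/iterations".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `iterations` | 100,000 | permutation draws per null; p-value grid 1/iterations (1e-5 at default) |
| `k` | 10 | swap attempts per rewiring = k × |I|; attempts, not accepted swaps, are counted, so runtime is bounded; k=0 returns the input graph |
| `min_universal` | 5 | keep terms annotating ≥ this many universal-network genes |
| `max_interesting` | 100 | keep terms annotating ≤ this many interesting-network genes |
| `weight_threshold` | off | drop edges whose weight is strictly below the threshold (a 500 threshold keeps a weight-500 edge) |

All counts (u_f, c_f, the filters) intersect gene sets with the relevant
network's node set: annotations of genes outside the universe are retained
in memory but never counted, because the sampling null draws from *U*.

Ties count toward every empirical p-value (the "≥" convention), so a draw
identical to the observed configuration is a success; a p-value of exactly
0 can still occur and is reported raw.

## Randomness and reproducibility

One integer seed drives a run.  Function-randomization draws use a per-term
substream derived from (seed, tag, crc32(term)), so a term's p-value does
not depend on which other terms are in the annotation file or on iteration
order.  Structure randomization generates one shared pool of rewired
networks per run, scored against every term — this matches the
per-iteration formulation and divides the rewiring cost by the number of
terms.  Uniform subsets are drawn by taking the u_f smallest of i.i.d.
uniform keys per draw, which is exactly uniform and vectorizes.  Identical
configuration and seed give byte-identical output files.

## Annotations

The true-path rule propagates each gene's annotations to all ancestors of
the annotating term, traversing a child→parent DAG supplied as a two-column
TSV or extracted from an OBO file.  Only `is_a` relations are traversed by
default (`part_of` is optional) — an assumption, since ontology relation
semantics vary; propagation is idempotent and only grows gene sets.  Terms
appearing only in the DAG acquire their descendants' genes; terms left
empty are dropped.  A cyclic DAG is an error that names one cycle.

## Synthetic data

The fixture generator produces networks from standard families — complete,
path, disjoint cliques, Erdős–Rényi, and preferential attachment (included
because the rewiring null is designed to preserve heavy-tailed degree
sequences) — and plants annotation terms that induce either one connected
component (chosen as a BFS prefix inside a sufficiently large component) or
a fragmented set (a greedy independent set, hence ≥ ⌈size/2⌉ components);
infeasible plants are errors.  These fixtures emulate the *contrast* the
method must detect — identical term sizes, opposite connectivity — not the
degree mixing, annotation-depth structure, or edge noise of a real
interactome, so passing tests demonstrate correctness of the statistics,
not biological recall on real networks.

The default study conditions for tests and the acceptance report are small
by design: six disjoint 4-cliques (24 nodes) for discrimination and merge
scoring, a 10-node edge-free network for the Fisher-equivalence check, and
1,000–100,000 iterations depending on the granularity the check needs.
These sizes make every statistic exactly auditable (the cliques' null
probabilities are enumerable by hand) while exercising the same code paths
an organism-scale run would.

## Numerical choices and degenerate inputs

* Empirical p-values are integer counts over iterations; no continuity
  correction or pseudo-count is added.
* Benjamini–Hochberg adjusted combined p-values are written as an extra
  column for the reader's benefit but never used for filtering.
* An all-singleton or empty H_f yields p_structure = 1 exactly (rewiring
  preserves the node set, and singletons are the order's minimum); an empty
  H_f also yields p_function = 1.  An all-singleton but non-empty H_f does
  *not* force p_function = 1, since a random draw can cover fewer
  interesting genes.
* Graphs with fewer than two edges cannot be rewired and are returned
  unchanged.
* Terms annotating no universal-network gene are skipped with a warning by
  the run driver; calling the sampler directly with such a term is an error.
* Input edges are normalized to simple undirected edges (self-loops and
  repeats dropped with logged counts); directionality is ignored throughout.

## Limitations

* Both nulls are Monte Carlo: p-values below 1/iterations are reported as
  0 and runtime grows linearly in iterations × (terms + k·|I|).
* Edge weights are used only for threshold filtering; the component-size
  statistic is unweighted.
* Functions are tested one at a time; overlapping terms yield correlated,
  redundant results, and no multiple-testing filter is applied.
* No identifier mapping is performed; gene identifiers are opaque,
  case-sensitive strings and must agree across all input files.
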