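"""Permutation statistics for network-based functional enrichment.

Given a universal network G = (U, I), an interesting network H = (C, J) with
C ⊆ U and J ⊆ I, and a function f annotating genes U_f, let H_f be the
subgraph of H induced by U_f ∩ C.  The connectivity of H_f is summarized by
cs(H_f), the non-increasing sequence of its component sizes, and judged
against two permutation nulls:

* **function randomization** — draw u_f = |U_f ∩ U| genes uniformly without
  replacement from U; the p-value is the fraction of draws X for which
  cs(H_X) ≥ cs(H_f).  With all edges removed this reduces exactly to the
  one-sided Fisher's exact test.
* **structure randomization** — rewire G by degree-preserving double edge
  swaps and re-induce H'_f in each rewired network; the p-value is the
  fraction of rewirings for which cs(H'_f) ≥ cs(H_f).

A function is called enriched only when both nulls reject, so the combined
p-value is the maximum of the two.  The merge score log10(p_r / p_a)
quantifies how much an added edge set improves a function's coherence.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .annotations import AnnotationSet
from .graph import (
    LESS,
    ComponentSizeSeq,
    compare_cs,
    component_size_seq,
    induced_subgraph,
)

logger = logging.getLogger(__name__)

# Substream tags so per-term function-randomization draws and the shared
# structure-randomization pool are independent and order-insensitive.
_FUNCTION_TAG = 1
_STRUCTURE_TAG = 2


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-function outcome of both permutation tests.

    ``p_combined`` is max(p_function, p_structure); ``fisher_p`` is the
    analytic hypergeometric baseline; ``p_bh`` is the Benjamini-Hochberg
    adjusted combined p-value across the run (reported, never filtered on).
    Empirical p-values lie on the grid {0, 1/iterations, ..., 1}; an exact 0
    means "< 1/iterations".
    """

    term: str
    u_f: int
    c_f: int
    cs_hf: ComponentSizeSeq
    fisher_p: float
    p_function: float
    p_structure: float
    p_combined: float
    iterations: int
    p_bh: float | None = None


@dataclass(frozen=True)
class MergeScoreResult:
    """Merge score for one function: s(f) = log10(p_without / p_with)."""

    term: str
    p_with: float
    p_without: float
    score: float


class PermutationPvalue(NamedTuple):
    pvalue: float
    observed_cs: ComponentSizeSeq


def empirical_pvalue(successes: int, iterations: int) -> float:
    """Empirical p-value successes/iterations.

    Successes are integer counts, so the smallest representable nonzero value
    is exactly 1/iterations (1e-5 at the default 100,000 iterations).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0 <= successes <= iterations:
        raise ValueError("successes must lie in [0, iterations]")
    return successes / iterations


def term_seed(seed: int, term: str, tag: int = _FUNCTION_TAG) -> np.random.SeedSequence:
    """Deterministic per-term RNG substream, independent of term order."""
    return np.random.SeedSequence([seed, tag, zlib.crc32(term.encode("utf-8"))])


def fisher_tail_pvalue(u: int, c: int, u_f: int, c_f: int) -> float:
    """One-sided Fisher / hypergeometric upper tail.

    Probability that a uniform draw of ``u_f`` genes from a universe of ``u``
    containing ``c`` interesting genes includes at least ``c_f`` interesting
    ones.  With u = c (whole-network mode) this is 1 for every term.
    """
    if c > u or u_f > u:
        raise ValueError("need c <= u and u_f <= u")
    if c_f > min(c, u_f):
        raise ValueError("need c_f <= min(c, u_f)")
    if min(u, c, u_f, c_f) < 0:
        raise ValueError("counts must be non-negative")
    return float(hypergeom.sf(c_f - 1, u, c, u_f))


# ---------------------------------------------------------------------------
# Restricted component sizes (hot path: plain dicts and ints, no nx.Graph)
# ---------------------------------------------------------------------------


def _component_sizes_restricted(members: Iterable, adj: Dict) -> ComponentSizeSeq:
    """Component sizes of the subgraph induced by ``members`` in an adjacency
    mapping; members missing from ``adj`` are isolated."""
    member_set = set(members)
    seen: Set = set()
    sizes: List[int] = []
    for start in member_set:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for w in adj.get(v, ()):
                if w in member_set and w not in seen:
                    seen.add(w)
                    stack.append(w)
        sizes.append(size)
    sizes.sort(reverse=True)
    return tuple(sizes)


# ---------------------------------------------------------------------------
# Function randomization
# ---------------------------------------------------------------------------


def function_randomization_pvalue(
    G: nx.Graph,
    H: nx.Graph,
    f_genes: Iterable[str],
    iterations: int,
    rng_seed,
    *,
    chunk_size: int = 4096,
) -> PermutationPvalue:
    """Empirical p-value of cs(H_f) under uniform resampling of gene sets.

    Draws ``u_f = |f_genes ∩ U|`` genes uniformly without replacement from
    G's node set, ``iterations`` times, and returns the fraction of draws X
    with cs(H_X) ≥ cs(H_f), together with the observed cs(H_f).

    Raises ``ValueError`` when u_f is 0 (no annotated gene in the universe).
    """
    universe = sorted(G.nodes)
    u = len(universe)
    f_in_u = set(f_genes) & set(universe)
    u_f = len(f_in_u)
    if u_f == 0:
        raise ValueError("function annotates no gene in the universal network")
    observed = component_size_seq(induced_subgraph(H, f_in_u))

    index = {g: i for i, g in enumerate(universe)}
    in_h = np.zeros(u, dtype=bool)
    for node in H.nodes:
        in_h[index[node]] = True
    adj = {index[n]: [index[m] for m in H[n]] for n in H.nodes}

    rng = np.random.default_rng(rng_seed)
    successes = 0
    done = 0
    while done < iterations:
        m = min(chunk_size, iterations - done)
        if u_f < u:
            # The u_f smallest of iid uniform keys form a uniform subset.
            keys = rng.random((m, u))
            picks = np.argpartition(keys, u_f - 1, axis=1)[:, :u_f]
        else:
            picks = np.broadcast_to(np.arange(u), (m, u))
        for row in picks:
            members = row[in_h[row]]
            sizes = _component_sizes_restricted((int(i) for i in members), adj)
            if compare_cs(sizes, observed) != LESS:
                successes += 1
        done += m
    return PermutationPvalue(empirical_pvalue(successes, iterations), observed)


# ---------------------------------------------------------------------------
# Structure randomization
# ---------------------------------------------------------------------------


class _EdgeSwapper:
    """Degree-preserving rewiring of a fixed base edge list.

    Each attempt picks two distinct edges uniformly, picks one of the two
    endpoint exchanges uniformly, and applies it unless it would create a
    self-loop or an edge already present (keeping the graph simple).
    Rejected attempts are consumed; every accepted swap preserves all node
    degrees.
    """

    def __init__(self, edges: Iterable[Tuple]):
        self.base = [tuple(sorted(e)) for e in edges]

    def randomized_edges(self, k: int, rng: np.random.Generator) -> List[Tuple]:
        m = len(self.base)
        edges = list(self.base)
        attempts = k * m
        if m < 2 or attempts == 0:
            return edges
        eset = set(edges)
        i_idx = rng.integers(0, m, size=attempts)
        j_off = rng.integers(0, m - 1, size=attempts)
        sides = rng.integers(0, 2, size=attempts)
        for t in range(attempts):
            i = int(i_idx[t])
            j = int(j_off[t])
            if j >= i:
                j += 1  # uniform over edges distinct from i
            a, b = edges[i]
            c, d = edges[j]
            if sides[t]:
                c, d = d, c
            if a == c or b == d:
                continue  # would create a self-loop
            e1 = (a, c) if a < c else (c, a)
            e2 = (b, d) if b < d else (d, b)
            if e1 in eset or e2 in eset:
                continue  # would duplicate an existing edge
            eset.discard(edges[i])
            eset.discard(edges[j])
            eset.add(e1)
            eset.add(e2)
            edges[i] = e1
            edges[j] = e2
        return edges


def randomize_network(G: nx.Graph, k: int = 10, rng_seed=None) -> nx.Graph:
    """Degree-preserving randomization of ``G`` via k·|edges| swap attempts.

    The result has G's exact node set and degree sequence, stays simple and
    self-loop free.  ``k=0`` (or fewer than two edges) returns a copy of G.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(rng_seed)
    swapper = _EdgeSwapper(G.edges)
    out = nx.Graph()
    out.add_nodes_from(G.nodes)
    out.add_edges_from(swapper.randomized_edges(k, rng))
    return out


def structure_randomization_pvalue(
    G: nx.Graph,
    C: Iterable[str],
    f_genes: Iterable[str],
    iterations: int,
    k: int = 10,
    rng_seed=None,
    *,
    observed_cs: ComponentSizeSeq | None = None,
) -> PermutationPvalue:
    """Empirical p-value of cs(H_f) under degree-preserving rewiring of G.

    Each iteration rewires G with k·|I| swap attempts and induces H'_f on
    C ∩ f_genes in the rewired network; the p-value is the fraction of
    iterations with cs(H'_f) ≥ cs(H_f).

    By default the observed statistic is computed from the subgraph of G
    induced by C ∩ f_genes; pass ``observed_cs`` when the interesting network
    is not induced (its cs(H_f) must then come from the true H).
    """
    c_set = set(C)
    missing = c_set - set(G.nodes)
    if missing:
        raise ValueError(f"interesting genes absent from universal network: {sorted(missing)[:5]}")
    target = sorted(c_set & set(f_genes))
    if observed_cs is None:
        observed_cs = component_size_seq(induced_subgraph(G, target))

    rng = np.random.default_rng(rng_seed)
    swapper = _EdgeSwapper(G.edges)
    target_set = set(target)
    successes = 0
    for _ in range(iterations):
        edges = swapper.randomized_edges(k, rng)
        adj: Dict[str, List[str]] = {}
        for a, b in edges:
            if a in target_set and b in target_set:
                adj.setdefault(a, []).append(b)
                adj.setdefault(b, []).append(a)
        sizes = _component_sizes_restricted(target, adj)
        if compare_cs(sizes, observed_cs) != LESS:
            successes += 1
    return PermutationPvalue(empirical_pvalue(successes, iterations), observed_cs)


# ---------------------------------------------------------------------------
# Combination, merge score, and the per-run driver
# ---------------------------------------------------------------------------


def combine_pvalues(p_function: float, p_structure: float) -> float:
    """Combined p-value: a function must be called by both nulls, so take the
    maximum of the two."""
    for p in (p_function, p_structure):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return max(p_function, p_structure)


def merge_score(p_without: float, p_with: float, floor: float) -> float:
    """s(f) = log10(p_without / p_with), with exact zeros replaced by
    ``floor`` (typically 1/iterations) before the ratio.

    Positive scores mean the added edge set improved the function's network
    coherence (its p-value dropped).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    pw = p_without if p_without > 0 else floor
    pa = p_with if p_with > 0 else floor
    return float(np.log10(pw / pa))


def _validate_subgraph(G: nx.Graph, H: nx.Graph) -> None:
    extra_nodes = set(H.nodes) - set(G.nodes)
    if extra_nodes:
        raise ValueError(
            f"interesting network has nodes absent from the universal network: "
            f"{sorted(extra_nodes)[:10]}"
        )
    extra_edges = [e for e in H.edges if not G.has_edge(*e)]
    if extra_edges:
        raise ValueError(
            f"interesting network has edges absent from the universal network: "
            f"{sorted(tuple(sorted(e)) for e in extra_edges)[:10]}"
        )


def enrich(
    G: nx.Graph,
    H: nx.Graph,
    ann: AnnotationSet,
    iterations: int = 100_000,
    k: int = 10,
    rng_seed: int = 0,
) -> List[EnrichmentResult]:
    """Run both permutation tests for every term of ``ann``.

    ``ann`` should already be true-path propagated and count-filtered.  One
    shared pool of rewired universal networks (seeded from ``rng_seed``)
    serves all terms' structure-randomization p-values; function
    randomization uses a per-term substream, so per-term results do not
    depend on which other terms are present.  Results are sorted by
    (p_combined, u_f, term).
    """
    _validate_subgraph(G, H)
    u_nodes = set(G.nodes)
    c_nodes = set(H.nodes)
    logger.info(
        "enrich: |U|=%d |I|=%d |C|=%d |J|=%d, %d term(s), %d iterations (grid 1/%d), k=%d",
        len(u_nodes), G.number_of_edges(), len(c_nodes), H.number_of_edges(),
        len(ann.terms), iterations, iterations, k,
    )
    logger.info("u_f counts are |U_f ∩ U|: genes outside the universal network never count")

    terms = sorted(ann.terms)
    records: List[dict] = []
    for term in terms:
        genes = set(ann.terms[term])
        u_f = len(genes & u_nodes)
        if u_f == 0:
            logger.warning("term %s annotates no universal-network gene; skipped", term)
            continue
        c_f = len(genes & c_nodes)
        cs_hf = component_size_seq(induced_subgraph(H, genes))
        fisher = fisher_tail_pvalue(len(u_nodes), len(c_nodes), u_f, c_f)
        p_fun, _ = function_randomization_pvalue(
            G, H, genes, iterations, term_seed(rng_seed, term, _FUNCTION_TAG)
        )
        records.append(
            dict(term=term, genes=genes, u_f=u_f, c_f=c_f, cs_hf=cs_hf,
                 fisher_p=fisher, p_function=p_fun)
        )

    # Shared structure-randomization pool: one rewired G' per iteration,
    # scored against every term's observed cs(H_f) (from the true H).
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, _STRUCTURE_TAG]))
    swapper = _EdgeSwapper(G.edges)
    targets = [sorted(r["genes"] & c_nodes) for r in records]
    target_sets = [set(t) for t in targets]
    counts = [0] * len(records)
    for _ in range(iterations):
        edges = swapper.randomized_edges(k, rng)
        for idx, rec in enumerate(records):
            tset = target_sets[idx]
            adj: Dict[str, List[str]] = {}
            for a, b in edges:
                if a in tset and b in tset:
                    adj.setdefault(a, []).append(b)
                    adj.setdefault(b, []).append(a)
            sizes = _component_sizes_restricted(targets[idx], adj)
            if compare_cs(sizes, rec["cs_hf"]) != LESS:
                counts[idx] += 1

    results = []
    for idx, rec in enumerate(records):
        p_struct = empirical_pvalue(counts[idx], iterations)
        results.append(
            EnrichmentResult(
                term=rec["term"],
                u_f=rec["u_f"],
                c_f=rec["c_f"],
                cs_hf=rec["cs_hf"],
                fisher_p=rec["fisher_p"],
                p_function=rec["p_function"],
                p_structure=p_struct,
                p_combined=combine_pvalues(rec["p_function"], p_struct),
                iterations=iterations,
            )
        )
    if results:
        adjusted = false_discovery_control([r.p_combined for r in results], method="bh")
        results = [replace(r, p_bh=float(q)) for r, q in zip(results, adjusted)]
    results.sort(key=lambda r: (r.p_combined, r.u_f, r.term))
    return results


def merge_compare(
    G: nx.Graph,
    removable_edges: Iterable[Tuple[str, str]],
    ann: AnnotationSet,
    iterations: int = 100_000,
    k: int = 10,
    rng_seed: int = 0,
    keep_edges: Iterable[Tuple[str, str]] = (),
) -> List[MergeScoreResult]:
    """Score how an edge set improves each function's network coherence.

    Runs :func:`enrich` twice with the same universal network and seed: once
    with the interesting network equal to G (all edges), once with the
    removable edges deleted from it — except edges also in ``keep_edges``
    (independent supporting evidence).  Node sets are unchanged.  Scores are
    s(f) = log10(p_without / p_with) on the combined p-values, with zeros
    floored at 1/iterations, sorted descending.
    """
    keep = {tuple(sorted(e)) for e in keep_edges}
    removable = {tuple(sorted(e)) for e in removable_edges} - keep
    H_without = nx.Graph()
    H_without.add_nodes_from(G.nodes)
    H_without.add_edges_from(
        e for e in G.edges if tuple(sorted(e)) not in removable
    )
    with_results = enrich(G, G, ann, iterations=iterations, k=k, rng_seed=rng_seed)
    without_results = enrich(G, H_without, ann, iterations=iterations, k=k, rng_seed=rng_seed)
    p_without = {r.term: r.p_combined for r in without_results}
    floor = 1.0 / iterations
    scores = [
        MergeScoreResult(
            term=r.term,
            p_with=r.p_combined,
            p_without=p_without[r.term],
            score=merge_score(p_without[r.term], r.p_combined, floor),
        )
        for r in with_results
        if r.term in p_without
    ]
    scores.sort(key=lambda s: (-s.score, s.term))
    return scores
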