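"""Graph primitives for network-based enrichment.

Networks are simple undirected :class:`networkx.Graph` objects over opaque,
case-sensitive gene identifiers.  The connectivity statistic of a graph is
``cs``, the non-increasing sequence of its connected-component sizes, with a
total order defined by zero-padding the shorter sequence and comparing at the
first differing index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

#: Non-increasing tuple of positive component sizes; () for the empty graph.
ComponentSizeSeq = Tuple[int, ...]

LESS = -1
EQUAL = 0
GREATER = 1


@dataclass(frozen=True)
class NormalizationReport:
    """Counts of input records discarded while building a simple graph."""

    self_loops: int = 0
    duplicate_edges: int = 0


def normalize_graph(
    edges: Iterable[Tuple[Hashable, Hashable]],
    nodes: Iterable[Hashable] = (),
) -> tuple[nx.Graph, NormalizationReport]:
    """Build a simple undirected graph from raw (possibly directed, repeated,
    self-looped) edge records.

    Repeated edges in either orientation collapse to one undirected edge;
    self-loops are dropped.  ``nodes`` adds isolated nodes.  Returns the graph
    and a report of how many records were discarded; discards are also logged.
    """
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    self_loops = 0
    duplicates = 0
    for a, b in edges:
        if a == b:
            self_loops += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            duplicates += 1
            continue
        graph.add_edge(a, b)
    report = NormalizationReport(self_loops=self_loops, duplicate_edges=duplicates)
    if self_loops or duplicates:
        logger.info(
            "normalized graph: dropped %d self-loop(s) and %d repeated edge(s)",
            self_loops,
            duplicates,
        )
    return graph, report


def induced_subgraph(net: nx.Graph, genes: Iterable[Hashable]) -> nx.Graph:
    """Subgraph of ``net`` induced by ``genes``.

    Genes absent from ``net`` are silently ignored.  Returns a mutable copy,
    never a frozen view.
    """
    keep = set(genes) & set(net.nodes)
    return nx.Graph(net.subgraph(keep))


def component_size_seq(net: nx.Graph) -> ComponentSizeSeq:
    """``cs(net)``: connected-component sizes, sorted non-increasing.

    Isolated nodes contribute size-1 entries; the empty graph yields ``()``.
    """
    return tuple(sorted((len(c) for c in nx.connected_components(net)), reverse=True))


def compare_cs(a: Sequence[int], b: Sequence[int]) -> int:
    """Three-way comparison of two component-size sequences.

    The shorter sequence is zero-padded to the longer length; sequences are
    equal iff entrywise equal, otherwise the first differing index decides.
    Returns ``LESS`` (-1), ``EQUAL`` (0) or ``GREATER`` (1).

    This is a total order on valid (non-increasing, positive) sequences, with
    the all-singletons sequence the minimum among graphs on a fixed node set.
    """
    n = max(len(a), len(b))
    for i in range(n):
        ai = a[i] if i < len(a) else 0
        bi = b[i] if i < len(b) else 0
        if ai < bi:
            return LESS
        if ai > bi:
            return GREATER
    return EQUAL
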