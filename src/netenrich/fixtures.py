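"""Deterministic synthetic networks and annotations.

Every statistic in the package is testable without external interactomes:
this module generates small networks from standard families (complete, path,
disjoint cliques, Erdős–Rényi, preferential attachment — the last because
the rewiring null is designed to preserve heavy-tailed degree sequences) and
plants annotation terms whose induced subgraphs are, by construction, either
a single connected component or highly fragmented.  Fixtures can be written
to disk in the same formats the CLI reads, for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx
import numpy as np

from .annotations import AnnotationSet
from .graph import component_size_seq, induced_subgraph

GENERATORS = (
    "complete",
    "path",
    "disjoint-cliques",
    "erdos-renyi",
    "preferential-attachment",
)


@dataclass(frozen=True)
class PlantedTerm:
    """A term to plant: ``connected`` terms induce one component,
    ``fragmented`` terms induce at least ⌈size/2⌉ components."""

    term: str
    size: int
    mode: str  # 'connected' | 'fragmented'


@dataclass(frozen=True)
class FixtureSpec:
    generator: str
    n_nodes: int
    edge_param: float = 0.0  # clique size / edge probability / attachment m
    planted: Tuple[PlantedTerm, ...] = ()
    seed: int = 0


def _node_name(i: int) -> str:
    return f"g{i:03d}"


def _build_graph(spec: FixtureSpec, rng: np.random.Generator) -> nx.Graph:
    n = spec.n_nodes
    if n < 1:
        raise ValueError("n_nodes must be >= 1")
    sub_seed = int(rng.integers(0, 2**31 - 1))
    if spec.generator == "complete":
        base = nx.complete_graph(n)
    elif spec.generator == "path":
        base = nx.path_graph(n)
    elif spec.generator == "disjoint-cliques":
        q = int(spec.edge_param)
        if q < 1:
            raise ValueError("disjoint-cliques needs a positive clique size")
        base = nx.Graph()
        base.add_nodes_from(range(n))
        for start in range(0, n, q):
            members = range(start, min(start + q, n))
            base.add_edges_from(
                (a, b) for i, a in enumerate(members) for b in list(members)[i + 1:]
            )
    elif spec.generator == "erdos-renyi":
        base = nx.gnp_random_graph(n, float(spec.edge_param), seed=sub_seed)
    elif spec.generator == "preferential-attachment":
        m = max(1, int(spec.edge_param))
        base = nx.barabasi_albert_graph(n, m, seed=sub_seed)
    else:
        raise ValueError(f"unknown generator {spec.generator!r}")
    return nx.relabel_nodes(base, {i: _node_name(i) for i in base.nodes})


def _plant_connected(net: nx.Graph, size: int, rng: np.random.Generator) -> FrozenSet[str]:
    components = [sorted(c) for c in nx.connected_components(net) if len(c) >= size]
    if not components:
        raise ValueError(
            f"cannot plant a connected term of size {size}: no component that large"
        )
    component = components[int(rng.integers(len(components)))]
    start = component[int(rng.integers(len(component)))]
    # BFS from a random start guarantees the first `size` visited nodes
    # induce a connected subgraph.
    chosen: List[str] = []
    for node in nx.bfs_tree(net, start):
        chosen.append(node)
        if len(chosen) == size:
            break
    return frozenset(chosen)


def _plant_fragmented(net: nx.Graph, size: int, rng: np.random.Generator) -> FrozenSet[str]:
    order = list(net.nodes)
    rng.shuffle(order)
    chosen: List[str] = []
    for node in order:
        if all(not net.has_edge(node, other) for other in chosen):
            chosen.append(node)
        if len(chosen) == size:
            break
    if len(chosen) < size:
        raise ValueError(
            f"cannot plant a fragmented term of size {size}: "
            f"no independent set that large found"
        )
    return frozenset(chosen)


def generate(spec: FixtureSpec) -> Tuple[nx.Graph, AnnotationSet]:
    """Generate the network and planted annotations for ``spec``.

    Deterministic for a fixed spec (seed included).  Raises ``ValueError``
    for infeasible plants; each planted term's mode contract is asserted
    after construction.
    """
    rng = np.random.default_rng(spec.seed)
    net = _build_graph(spec, rng)
    terms: Dict[str, FrozenSet[str]] = {}
    for planted in spec.planted:
        if planted.size < 1 or planted.size > net.number_of_nodes():
            raise ValueError(f"planted term {planted.term}: infeasible size {planted.size}")
        if planted.mode == "connected":
            genes = _plant_connected(net, planted.size, rng)
            cs = component_size_seq(induced_subgraph(net, genes))
            assert cs == (planted.size,), cs
        elif planted.mode == "fragmented":
            genes = _plant_fragmented(net, planted.size, rng)
            cs = component_size_seq(induced_subgraph(net, genes))
            assert len(cs) >= ceil(planted.size / 2), cs
        else:
            raise ValueError(f"unknown planted mode {planted.mode!r}")
        terms[planted.term] = genes
    return net, AnnotationSet(terms=terms)


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a 2-column TSV edge list (isolated nodes are lost; use a node
    list alongside if they matter)."""
    with open(path, "w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            handle.write(f"{a}\t{b}\n")


def write_node_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        for node in sorted(net.nodes):
            handle.write(f"{node}\n")


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    """Write annotations in GMT format (name, description, genes...)."""
    with open(path, "w") as handle:
        for term in sorted(ann.terms):
            genes = "\t".join(sorted(ann.terms[term]))
            handle.write(f"{term}\tsynthetic\t{genes}\n")
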