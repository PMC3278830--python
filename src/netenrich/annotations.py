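"""Gene-to-function annotations, true-path propagation, and count filters.

An :class:`AnnotationSet` maps function identifiers (GO terms, MSigDB set
names, ...) to sets of gene identifiers, optionally together with an ontology
DAG given as (child, parent) pairs.  The true-path rule propagates every
gene's annotations to all ancestors of the annotating term, so that a parent
term always annotates at least the genes of its children.

Annotations of genes absent from the universal network are retained here but
never counted by the enrichment statistics, which intersect each gene set
with the relevant network's node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

DagEdge = Tuple[str, str]  # (child, parent)


@dataclass(frozen=True)
class AnnotationSet:
    """Mapping from function identifier to annotated gene set.

    ``dag``, when present, is a set of (child, parent) pairs and must be
    acyclic.  After :func:`propagate_true_path`, genes(child) ⊆ genes(parent)
    for every pair.
    """

    terms: Dict[str, FrozenSet[str]]
    dag: FrozenSet[DagEdge] | None = None

    def genes(self, term: str) -> FrozenSet[str]:
        return self.terms[term]

    def __len__(self) -> int:
        return len(self.terms)


def propagate_true_path(ann: AnnotationSet) -> AnnotationSet:
    """Apply the true-path rule: annotate every gene to all ancestors of its
    annotating terms.

    Terms appearing only in the DAG acquire their descendants' genes; terms
    that remain empty afterwards are dropped.  Idempotent and monotone (gene
    sets only grow).  Raises ``ValueError`` naming a cycle if the DAG is not
    acyclic.
    """
    if ann.dag is None:
        return ann
    dag = nx.DiGraph()
    dag.add_nodes_from(ann.terms)
    dag.add_edges_from(ann.dag)  # edges point child -> parent
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"annotation DAG contains a cycle: {cycle}")

    genes: Dict[str, Set[str]] = {t: set(ann.terms.get(t, ())) for t in dag.nodes}
    # Children precede parents in topological order of child->parent edges,
    # so a single pass accumulates all descendants transitively.
    for term in nx.topological_sort(dag):
        for parent in dag.successors(term):
            genes[parent] |= genes[term]
    terms = {t: frozenset(g) for t, g in genes.items() if g}
    return AnnotationSet(terms=terms, dag=ann.dag)


def filter_functions(
    ann: AnnotationSet,
    universal: nx.Graph,
    interesting: nx.Graph,
    min_universal: int = 5,
    max_interesting: int = 100,
) -> AnnotationSet:
    """Retain terms annotating at least ``min_universal`` genes in the
    universal network and at most ``max_interesting`` genes in the
    interesting network (both bounds inclusive).

    Counts intersect each gene set with the respective node set, so genes
    absent from a network never count.
    """
    if min_universal <= 0 or max_interesting <= 0:
        raise ValueError("count thresholds must be positive")
    u_nodes = set(universal.nodes)
    c_nodes = set(interesting.nodes)
    kept = {
        term: genes
        for term, genes in ann.terms.items()
        if len(genes & u_nodes) >= min_universal
        and len(genes & c_nodes) <= max_interesting
    }
    logger.info(
        "function filter (>=%d universal, <=%d interesting): %d of %d terms kept",
        min_universal,
        max_interesting,
        len(kept),
        len(ann.terms),
    )
    return AnnotationSet(terms=kept, dag=ann.dag)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _build_terms(pairs: Iterable[Tuple[str, str]]) -> Dict[str, FrozenSet[str]]:
    acc: Dict[str, Set[str]] = {}
    for gene, term in pairs:
        acc.setdefault(term, set()).add(gene)
    return {t: frozenset(g) for t, g in acc.items() if g}


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file (tab-separated: set name, description, member genes).

    Duplicate genes within a set collapse silently; records with no member
    genes are dropped.
    """
    terms: Dict[str, FrozenSet[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT record needs name, description and "
                    f"at least one gene (got {len(fields)} field(s))"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if genes:
                terms[name] = terms.get(name, frozenset()) | genes
    return AnnotationSet(terms=terms)


def read_gene_term_tsv(path: str | Path) -> AnnotationSet:
    """Read two-column (gene, term) TSV annotations; duplicates collapse."""
    pairs = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene and term columns")
            pairs.append((fields[0], fields[1]))
    return AnnotationSet(terms=_build_terms(pairs))


def read_dag_tsv(path: str | Path) -> FrozenSet[DagEdge]:
    """Read a two-column child→parent TSV describing the ontology DAG."""
    edges: Set[DagEdge] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected child and parent columns")
            edges.add((fields[0], fields[1]))
    return frozenset(edges)


def read_obo_dag(path: str | Path, include_part_of: bool = False) -> FrozenSet[DagEdge]:
    """Extract child→parent term pairs from an OBO ontology file.

    Traverses ``is_a`` relations only by default; set ``include_part_of`` to
    also treat ``part_of`` as a parent relation.
    """
    import obonet

    graph = obonet.read_obo(path)
    wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
    edges: Set[DagEdge] = set()
    for child, parent, key in graph.edges(keys=True):
        if key in wanted:
            edges.add((child, parent))
    return frozenset(edges)
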