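"""Readers, writers, run configuration and drivers.

Input formats: 2/3-column edge-list TSV (source, target[, weight]) or SIF,
plain node lists, GMT / two-column TSV annotations, child→parent DAG TSV or
OBO.  Output: a fixed-format results TSV plus a JSON run manifest (config,
seed, package versions) written beside it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from . import __version__
from .annotations import (
    AnnotationSet,
    filter_functions,
    propagate_true_path,
    read_dag_tsv,
    read_gene_term_tsv,
    read_gmt,
    read_obo_dag,
)
from .enrichment import EnrichmentResult, MergeScoreResult, enrich, merge_compare
from .graph import induced_subgraph, normalize_graph

logger = logging.getLogger(__name__)

# Fixed output formats (documented in the results header line): p-values use
# 6-significant-digit scientific notation, merge scores 4 decimals, so files
# round-trip exactly as formatted.
_PVAL_FMT = "{:.6e}"
_SCORE_FMT = "{:.4f}"

RESULT_COLUMNS = [
    "term", "u_f", "c_f", "cs", "fisher_p",
    "p_function", "p_structure", "p_combined", "bh_adjusted",
]
MERGE_COLUMNS = ["term", "p_with", "p_without", "score"]


@dataclass
class RunConfig:
    """Configuration of one enrichment run."""

    universal: str
    interesting_edges: Optional[str] = None
    interesting_nodes: Optional[str] = None
    annotations: str = ""
    annotation_format: str = "auto"  # auto | gmt | tsv
    dag: Optional[str] = None  # child->parent TSV or .obo
    iterations: int = 100_000
    k: int = 10
    min_universal: int = 5
    max_interesting: int = 100
    weight_threshold: Optional[float] = None
    seed: int = 0
    output: str = "results.tsv"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.weight_threshold is not None and self.weight_threshold < 0:
            raise ValueError("weight threshold must be >= 0")


# ---------------------------------------------------------------------------
# Network / list readers
# ---------------------------------------------------------------------------


def read_network(path: str | Path, weight_threshold: Optional[float] = None) -> nx.Graph:
    """Read an edge list (TSV: source, target[, weight]; or SIF: source,
    interaction type, targets...) into a normalized simple undirected graph.

    Edges with weight strictly below ``weight_threshold`` are dropped (a
    threshold of 500 keeps a weight-500 edge).  Self-loops and repeated edges
    are removed with logged counts.  Malformed lines raise with their number.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    raw_edges: List[Tuple[str, str]] = []
    lone_nodes: List[str] = []
    dropped_low_weight = 0
    n_lines = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t") if "\t" in line else line.split()
            if is_sif:
                if len(fields) == 1:
                    lone_nodes.append(fields[0])
                    continue
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF needs source, interaction and target"
                    )
                raw_edges.extend((fields[0], tgt) for tgt in fields[2:])
                continue
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least source and target columns"
                )
            if weight_threshold is not None:
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: weight threshold set but no weight column"
                    )
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from exc
                if weight < weight_threshold:
                    dropped_low_weight += 1
                    continue
            raw_edges.append((fields[0], fields[1]))
    graph, report = normalize_graph(raw_edges, nodes=lone_nodes)
    if n_lines == 0:
        logger.warning("%s: empty network file", path)
    logger.info(
        "%s: %d nodes, %d edges after normalization "
        "(%d self-loop(s), %d repeat(s), %d low-weight edge(s) dropped)",
        path, graph.number_of_nodes(), graph.number_of_edges(),
        report.self_loops, report.duplicate_edges, dropped_low_weight,
    )
    return graph


def read_node_list(path: str | Path) -> Set[str]:
    """Read one gene identifier per line (extra columns ignored)."""
    nodes: Set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            nodes.add(line.split()[0])
    return nodes


def read_edge_pairs(path: str | Path) -> Set[Tuple[str, str]]:
    """Read a 2-column TSV into a set of unordered edge pairs."""
    pairs: Set[Tuple[str, str]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            pairs.add(tuple(sorted(fields[:2])))
    return pairs


def read_annotations(path: str | Path, fmt: str = "auto") -> AnnotationSet:
    """Read annotations from GMT or two-column (gene, term) TSV.

    ``fmt='auto'`` treats ``.gmt`` files as GMT and everything else as TSV.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if fmt == "gmt":
        return read_gmt(path)
    if fmt == "tsv":
        return read_gene_term_tsv(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def read_dag(path: str | Path):
    """Read an ontology DAG from a child→parent TSV or an ``.obo`` file."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return read_obo_dag(path)
    return read_dag_tsv(path)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _format_results(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.term,
                "u_f": r.u_f,
                "c_f": r.c_f,
                "cs": ",".join(str(s) for s in r.cs_hf),
                "fisher_p": _PVAL_FMT.format(r.fisher_p),
                "p_function": _PVAL_FMT.format(r.p_function),
                "p_structure": _PVAL_FMT.format(r.p_structure),
                "p_combined": _PVAL_FMT.format(r.p_combined),
                "bh_adjusted": _PVAL_FMT.format(r.p_bh) if r.p_bh is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV (p-values in %.6e, cs comma-joined)."""
    _format_results(results).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV with every field as the formatted string."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_merge_results(results: Iterable[MergeScoreResult], path: str | Path) -> None:
    """Write merge-score rows as TSV (p-values %.6e, score %.4f)."""
    rows = [
        {
            "term": r.term,
            "p_with": _PVAL_FMT.format(r.p_with),
            "p_without": _PVAL_FMT.format(r.p_without),
            "score": _SCORE_FMT.format(r.score),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=MERGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> Path:
    """Write the JSON run manifest next to ``path`` and return its location."""
    import networkx
    import numpy
    import scipy

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "pvalue_grid": 1.0 / config.iterations,
        "versions": {
            "netenrich": __version__,
            "python": sys.version.split()[0],
            "networkx": networkx.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    out = Path(str(path) + ".manifest.json")
    with open(out, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def _load_annotations(config: RunConfig, universal: nx.Graph, interesting: nx.Graph) -> AnnotationSet:
    ann = read_annotations(config.annotations, config.annotation_format)
    if config.dag:
        ann = AnnotationSet(terms=ann.terms, dag=read_dag(config.dag))
        ann = propagate_true_path(ann)
    return filter_functions(
        ann, universal, interesting,
        min_universal=config.min_universal,
        max_interesting=config.max_interesting,
    )


def load_interesting(config: RunConfig, universal: nx.Graph) -> nx.Graph:
    """Resolve the interesting network from config: explicit edge list, node
    list (induced subgraph), or whole-network mode (H = G)."""
    if config.interesting_edges and config.interesting_nodes:
        raise ValueError("give an interesting edge list or a node list, not both")
    if config.interesting_edges:
        return read_network(config.interesting_edges, config.weight_threshold)
    if config.interesting_nodes:
        return induced_subgraph(universal, read_node_list(config.interesting_nodes))
    return universal


def run_enrichment(config: RunConfig) -> List[EnrichmentResult]:
    """Load inputs per ``config``, run both permutation tests, write the
    results TSV and manifest, and return the results."""
    universal = read_network(config.universal, config.weight_threshold)
    interesting = load_interesting(config, universal)
    ann = _load_annotations(config, universal, interesting)
    results = enrich(
        universal, interesting, ann,
        iterations=config.iterations, k=config.k, rng_seed=config.seed,
    )
    write_results(results, config.output)
    write_manifest(config, config.output)
    return results


def run_merge_compare(
    config: RunConfig,
    removable_path: str | Path,
    keep_path: Optional[str | Path] = None,
) -> List[MergeScoreResult]:
    """merge-compare driver: score every function's coherence gain from the
    removable edge set; writes TSV + manifest and returns sorted scores."""
    universal = read_network(config.universal, config.weight_threshold)
    removable = read_edge_pairs(removable_path)
    keep = read_edge_pairs(keep_path) if keep_path else set()
    ann = _load_annotations(config, universal, universal)
    results = merge_compare(
        universal, removable, ann,
        iterations=config.iterations, k=config.k, rng_seed=config.seed,
        keep_edges=keep,
    )
    write_merge_results(results, config.output)
    write_manifest(
        config, config.output,
        extra={"removable_edges": str(removable_path), "kept_edges": len(keep)},
    )
    return results
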