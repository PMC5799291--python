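"""Construction of the gene-gene network induced by intragenic miRNAs.

A directed edge A ⊣ B means: gene A hosts an intragenic miRNA whose mature
form has B among its validated targets.  Edges therefore represent
(predominantly repressive) intergenic regulation mediated by the hosted
miRNA.  The analysed graph is *simple*: self-loops (a gene targeted by its
own intragenic miRNA) are recorded in a side table and removed, parallel
edges arising from several miRNAs are merged with their miRNA labels
unioned, and nodes left without any incident edge are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .annotation_io import (
    MaturePrecursorMap,
    MirnaGeneAnnotation,
    ValidatedTargetSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NetworkSummary",
    "build_network",
    "summarize_network",
    "in_degree_ranking",
    "in_degree_histogram",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]


@dataclass(frozen=True)
class GeneNetwork:
    """A simple directed gene-gene graph with miRNA-labelled edges.

    ``edges`` maps each ordered gene pair (source, target) to the set of
    mature miRNAs mediating the interaction.  ``nodes`` normally equals the
    set of edge endpoints (no isolated nodes); random-graph samples may carry
    extra declared nodes so that triad-census identities hold on the full
    vertex set.  ``self_loops`` records loops removed during simplification
    (gene -> miRNAs targeting their own host); ``provenance`` records, for
    each retained edge, the (mature miRNA, precursor, host gene) triples that
    produced it.
    """

    edges: Mapping[tuple[str, str], frozenset[str]]
    nodes: frozenset[str] = field(default=None)  # type: ignore[assignment]
    self_loops: Mapping[str, frozenset[str]] = field(default_factory=dict)
    provenance: frozenset[tuple[str, str, str]] = frozenset()

    def __post_init__(self) -> None:
        endpoints = frozenset(g for pair in self.edges for g in pair)
        if self.nodes is None:
            object.__setattr__(self, "nodes", endpoints)
        else:
            object.__setattr__(self, "nodes", frozenset(self.nodes) | endpoints)
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} in a simplified network")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self, gene: str) -> int:
        return sum(1 for (u, _v) in self.edges if u == gene)

    def in_degree(self, gene: str) -> int:
        return sum(1 for (_u, v) in self.edges if v == gene)

    def to_networkx(self) -> nx.DiGraph:
        """The graph as a :class:`networkx.DiGraph` (miRNA labels on edges)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), mirnas in self.edges.items():
            g.add_edge(u, v, mirnas=sorted(mirnas))
        return g


@dataclass(frozen=True)
class NetworkSummary:
    """Node-role and annotation counts of a simplified network.

    Identities: ``total_n == bothdir_n + out_n + in_n`` and
    ``host_genes == bothdir_n + out_n``.
    """

    total_n: int
    bothdir_n: int
    out_n: int
    in_n: int
    total_e: int
    mat_mi: int
    pre_mi: int
    host_genes: int

    def as_dict(self) -> dict[str, int]:
        return {
            "total_n": self.total_n,
            "bothdir_n": self.bothdir_n,
            "out_n": self.out_n,
            "in_n": self.in_n,
            "total_e": self.total_e,
            "mat_mi": self.mat_mi,
            "pre_mi": self.pre_mi,
            "host_genes": self.host_genes,
        }


def build_network(
    annotations: Sequence[MirnaGeneAnnotation],
    mat_map: MaturePrecursorMap,
    targets: ValidatedTargetSet,
) -> GeneNetwork:
    """Build the simplified host-gene → target-gene network.

    A raw edge host → target is created for every validated
    (mature miRNA, target) pair such that one of the mature miRNA's
    precursors is annotated inside a host gene.  Mature miRNAs deriving from
    precursors in several host genes contribute an edge from every host.
    Simplification then removes loops, merges parallel edges (miRNA labels
    unioned) and drops isolated nodes.
    """
    if not targets:
        logger.warning("empty validated target set: the network is empty")
    hosts_of_pre: dict[str, set[str]] = {}
    for rec in annotations:
        hosts_of_pre.setdefault(rec.pre_mirna_id, set()).add(rec.host_gene)

    merged: dict[tuple[str, str], set[str]] = {}
    loops: dict[str, set[str]] = {}
    provenance: set[tuple[str, str, str]] = set()
    for mature, target in targets:
        for pre in mat_map.get(mature, ()):  # unmapped matures induce nothing
            for host in hosts_of_pre.get(pre, ()):
                if host == target:
                    loops.setdefault(host, set()).add(mature)
                    continue
                merged.setdefault((host, target), set()).add(mature)
                provenance.add((mature, pre, host))
    return GeneNetwork(
        edges={pair: frozenset(ms) for pair, ms in merged.items()},
        self_loops={g: frozenset(ms) for g, ms in loops.items()},
        provenance=frozenset(provenance),
    )


def summarize_network(net: GeneNetwork) -> NetworkSummary:
    """Summary counts of a built network.

    Node roles are computed on the simplified graph; miRNA, precursor and
    host counts cover only miRNAs that induce at least one retained edge
    (taken from the network's provenance records).
    """
    sources = {u for (u, _v) in net.edges}
    sinks = {v for (_u, v) in net.edges}
    both = sources & sinks
    out_only = sources - sinks
    in_only = sinks - sources
    if net.provenance:
        matures = {m for (m, _p, _h) in net.provenance}
        pres = {p for (_m, p, _h) in net.provenance}
        hosts = {h for (_m, _p, h) in net.provenance}
    else:  # e.g. a network loaded from an edge list: fall back to edge labels
        matures = set().union(*net.edges.values()) if net.edges else set()
        pres = set()
        hosts = set()
    return NetworkSummary(
        total_n=len(both | out_only | in_only),
        bothdir_n=len(both),
        out_n=len(out_only),
        in_n=len(in_only),
        total_e=net.n_edges,
        mat_mi=len(matures),
        pre_mi=len(pres),
        host_genes=len(hosts) if hosts else len(sources),
    )


def in_degree_histogram(net: GeneNetwork) -> dict[int, int]:
    """Histogram in-degree -> number of nodes (zero in-degree included)."""
    indeg = {g: 0 for g in net.nodes}
    for (_u, v) in net.edges:
        indeg[v] += 1
    hist: dict[int, int] = {}
    for d in indeg.values():
        hist[d] = hist.get(d, 0) + 1
    return hist


def in_degree_ranking(net: GeneNetwork, k: int) -> list[tuple[str, int]]:
    """The ``k`` genes with the highest in-degree.

    Sorted by in-degree descending with a lexicographic tie-break; if ``k``
    exceeds the node count the full ranking is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    indeg = {g: 0 for g in net.nodes}
    for (_u, v) in net.edges:
        indeg[v] += 1
    ranked = sorted(indeg.items(), key=lambda gv: (-gv[1], gv[0]))
    return ranked[:k]


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write the edge list as TSV: source_gene, target_gene, mirna_ids.

    miRNA identifiers are semicolon-joined, mirroring the formal-description
    worksheet layout used to publish such networks.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source_gene\ttarget_gene\tmirna_ids\n")
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{';'.join(sorted(net.edges[(u, v)]))}\n")


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read an edge-list TSV, simplifying on load.

    Published edge lists may or may not be pre-simplified: loops are dropped
    and duplicate ordered pairs merged here, and a log message reports
    whether anything changed (round-trips of :func:`write_edge_list` never
    do).
    """
    merged: dict[tuple[str, str], set[str]] = {}
    loops: dict[str, set[str]] = {}
    n_raw = 0
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["source_gene", "target_gene"]
        if header[: len(required)] != required:
            raise ValueError(f"{path}: expected columns {required}, got {header[:2]}")
        has_mirnas = len(header) > 2 and header[2] == "mirna_ids"
        for line in fh:
            if not line.strip():
                continue
            n_raw += 1
            parts = line.rstrip("\n").split("\t")
            u, v = parts[0].strip().upper(), parts[1].strip().upper()
            mirnas = (
                {m for m in parts[2].split(";") if m} if has_mirnas and len(parts) > 2 else set()
            )
            if u == v:
                loops.setdefault(u, set()).update(mirnas)
                continue
            merged.setdefault((u, v), set()).update(mirnas)
    if n_raw != len(merged):
        logger.info(
            "%s: simplification changed the edge list (%d rows -> %d edges)",
            path,
            n_raw,
            len(merged),
        )
    return GeneNetwork(
        edges={pair: frozenset(ms) for pair, ms in merged.items()},
        self_loops={g: frozenset(ms) for g, ms in loops.items()},
    )


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    """Export the network as GraphML for visualisation tools."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for (u, v), mirnas in net.edges.items():
        g.add_edge(u, v, mirnas=";".join(sorted(mirnas)))
    nx.write_graphml(g, str(path))
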