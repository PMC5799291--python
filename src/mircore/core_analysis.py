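"""Network core: nontrivial strongly connected components and their union.

The *core* of the gene-gene network is the union of all strongly connected
components (SCCs) with at least two nodes.  Each such component is a set of
genes in which every gene is (possibly indirectly) regulated by a miRNA
hosted in another member, and in turn hosts a miRNA regulating a member —
the multi-gene analogue of a self-regulating host gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .network_build import GeneNetwork

__all__ = [
    "CoreDecomposition",
    "extract_core",
    "core_subgraph",
    "core_degree_ranking",
    "core_report",
]


@dataclass(frozen=True)
class CoreDecomposition:
    """Nontrivial SCCs of a network, largest first.

    ``components`` are pairwise disjoint gene sets of size >= 2, ordered by
    decreasing size with ties broken by the lexicographically smallest
    member; ``core`` is their union.
    """

    components: tuple[frozenset[str], ...]

    @property
    def core(self) -> frozenset[str]:
        return frozenset().union(*self.components) if self.components else frozenset()

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)


def extract_core(net: GeneNetwork) -> CoreDecomposition:
    """All SCCs of size >= 2.  An acyclic network yields an empty core."""
    g = net.to_networkx()
    comps = [frozenset(c) for c in nx.strongly_connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return CoreDecomposition(tuple(comps))


def core_subgraph(net: GeneNetwork, dec: CoreDecomposition) -> GeneNetwork:
    """The subgraph of ``net`` induced by the core nodes.

    All edges with both endpoints in the core are retained, including edges
    running between two different components.
    """
    core = dec.core
    edges = {
        (u, v): mirnas for (u, v), mirnas in net.edges.items() if u in core and v in core
    }
    return GeneNetwork(edges=edges, nodes=core)


def core_degree_ranking(sub: GeneNetwork) -> list[tuple[str, int]]:
    """Genes of a core subgraph ranked by total (in + out) degree.

    Descending by degree, lexicographic tie-break.
    """
    deg = {g: 0 for g in sub.nodes}
    for (u, v) in sub.edges:
        deg[u] += 1
        deg[v] += 1
    return sorted(deg.items(), key=lambda gd: (-gd[1], gd[0]))


def core_report(net: GeneNetwork, dec: CoreDecomposition, path: str | Path | None = None) -> dict:
    """JSON-serialisable core report (components, sizes, induced edges)."""
    sub = core_subgraph(net, dec)
    report = {
        "n_components": len(dec.components),
        "component_sizes": list(dec.sizes),
        "components": [sorted(c) for c in dec.components],
        "core_size": len(dec.core),
        "induced_edges": [
            {"source": u, "target": v, "mirnas": sorted(ms)}
            for (u, v), ms in sorted(sub.edges.items())
        ],
        "degree_ranking": [{"gene": g, "degree": d} for g, d in core_degree_ranking(sub)],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2), encoding="utf-8")
    return report
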