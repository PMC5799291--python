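"""Triad census: three-node induced-subgraph isomorphism classes.

Every unordered triple of nodes in a simple directed graph induces one of
16 possible three-node digraphs up to isomorphism.  Classes are named with
the standard triad-census nomenclature ``003 … 300`` (digits: number of
mutual, asymmetric and null dyads, plus an orientation letter).  The main
counter delegates to the edge-based Batagelj–Mrvar algorithm, which scales
to graphs where enumerating all C(n,3) triples is impossible; an
independent brute-force counter (full triple enumeration against a
64-entry canonical code table built here from first principles) serves as
an oracle for it.

The three-node motif shapes highlighted in the study's figures are
registered as named, configurable constants (``FIG2A``/``FIG2B``/``FIG2C``)
because the figures, not the prose, define their adjacency patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb
from typing import Mapping

import networkx as nx

from .network_build import GeneNetwork

__all__ = [
    "TRIAD_CLASSES",
    "TRIAD_REPRESENTATIVES",
    "FULLY_MUTUAL",
    "TriadCensusResult",
    "triad_census",
    "brute_force_census",
    "count_motif",
    "count_motif_embeddings",
    "figure_motifs",
    "configure_figure_motifs",
]

#: The 16 isomorphism classes of 3-node directed graphs, as edge sets on
#: nodes {0, 1, 2}.  Naming follows the standard census nomenclature.
TRIAD_REPRESENTATIVES: dict[str, frozenset[tuple[int, int]]] = {
    "003": frozenset(),
    "012": frozenset({(0, 1)}),
    "102": frozenset({(0, 1), (1, 0)}),
    "021D": frozenset({(1, 0), (1, 2)}),
    "021U": frozenset({(0, 1), (2, 1)}),
    "021C": frozenset({(0, 1), (1, 2)}),
    "111D": frozenset({(0, 2), (2, 0), (1, 2)}),
    "111U": frozenset({(0, 2), (2, 0), (2, 1)}),
    "030T": frozenset({(0, 1), (2, 1), (0, 2)}),
    "030C": frozenset({(1, 0), (2, 1), (0, 2)}),
    "201": frozenset({(0, 1), (1, 0), (0, 2), (2, 0)}),
    "120D": frozenset({(1, 2), (1, 0), (0, 2), (2, 0)}),
    "120U": frozenset({(0, 1), (2, 1), (0, 2), (2, 0)}),
    "120C": frozenset({(0, 1), (1, 2), (0, 2), (2, 0)}),
    "210": frozenset({(0, 1), (1, 2), (2, 1), (0, 2), (2, 0)}),
    "300": frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}),
}

TRIAD_CLASSES: tuple[str, ...] = tuple(TRIAD_REPRESENTATIVES)

#: The triple in which every pair of genes is mutually connected.
FULLY_MUTUAL = "300"

_PAIR_BIT = {(0, 1): 1, (1, 0): 2, (0, 2): 4, (2, 0): 8, (1, 2): 16, (2, 1): 32}


def _edges_to_code(edges: frozenset[tuple[int, int]]) -> int:
    return sum(_PAIR_BIT[e] for e in edges)


def _permute_code(code: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for (i, j), bit in _PAIR_BIT.items():
        if code & bit:
            out |= _PAIR_BIT[(perm[i], perm[j])]
    return out


def _build_code_table() -> dict[int, str]:
    table: dict[int, str] = {}
    for name, edges in TRIAD_REPRESENTATIVES.items():
        rep = _edges_to_code(edges)
        for perm in permutations((0, 1, 2)):
            code = _permute_code(rep, perm)
            if code in table and table[code] != name:
                raise RuntimeError("triad representatives are not pairwise non-isomorphic")
            table[code] = name
    if len(table) != 64:
        raise RuntimeError("triad code table does not cover all 64 adjacency patterns")
    return table


#: code (6 adjacency bits of an ordered triple) -> class label
_CODE_TO_CLASS: dict[int, str] = _build_code_table()


@dataclass(frozen=True)
class TriadCensusResult:
    """Counts of the 16 triad classes over all node triples of a graph."""

    counts: Mapping[str, int]
    n_nodes: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {name: int(self.counts.get(name, 0)) for name in TRIAD_CLASSES}
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def triad_census(net: GeneNetwork) -> TriadCensusResult:
    """Census of all C(n, 3) node triples of a simplified network.

    Non-empty classes are enumerated from the edges; the sparse classes
    (003, 012, 102) are completed arithmetically, so the census identity
    Σ counts = C(n, 3) holds without touching every triple.
    """
    n = net.n_nodes
    if n < 3:
        return TriadCensusResult({}, n)
    g = net.to_networkx()
    counts = nx.triadic_census(g)
    return TriadCensusResult(counts, n)


def brute_force_census(net: GeneNetwork, *, max_nodes: int = 300) -> TriadCensusResult:
    """Naive census classifying every triple individually (test oracle).

    Refuses graphs above ``max_nodes`` nodes: enumeration is cubic and this
    routine exists to validate :func:`triad_census`, not to replace it.
    """
    n = net.n_nodes
    if n > max_nodes:
        raise ValueError(f"brute-force census refused: {n} nodes > guard of {max_nodes}")
    counts = dict.fromkeys(TRIAD_CLASSES, 0)
    edge_set = set(net.edges)
    nodes = sorted(net.nodes)
    for a, b, c in combinations(nodes, 3):
        code = 0
        if (a, b) in edge_set:
            code |= 1
        if (b, a) in edge_set:
            code |= 2
        if (a, c) in edge_set:
            code |= 4
        if (c, a) in edge_set:
            code |= 8
        if (b, c) in edge_set:
            code |= 16
        if (c, b) in edge_set:
            code |= 32
        counts[_CODE_TO_CLASS[code]] += 1
    return TriadCensusResult(counts, n)


def _check_label(motif: str) -> str:
    if motif not in TRIAD_REPRESENTATIVES:
        raise ValueError(f"unknown triad class {motif!r}; expected one of {TRIAD_CLASSES}")
    return motif


def count_motif(net: GeneNetwork, motif: str) -> int:
    """Number of node triples whose induced subgraph is of class ``motif``."""
    return triad_census(net).counts[_check_label(motif)]


def _contains(host: str, motif: str) -> bool:
    """Does the class ``host`` contain ``motif`` as a (non-induced) subgraph?"""
    host_edges = TRIAD_REPRESENTATIVES[host]
    motif_edges = TRIAD_REPRESENTATIVES[motif]
    for perm in permutations((0, 1, 2)):
        mapped = {(perm[i], perm[j]) for (i, j) in motif_edges}
        if mapped <= host_edges:
            return True
    return False


def count_motif_embeddings(net: GeneNetwork, motif: str) -> int:
    """Number of node triples containing ``motif`` as a not-necessarily-induced
    subgraph (sensitivity check for the induced-count convention)."""
    _check_label(motif)
    census = triad_census(net)
    return sum(census.counts[cls] for cls in TRIAD_CLASSES if _contains(cls, motif))


# ---------------------------------------------------------------------------
# Figure-bound motif constants.  The overrepresented shapes are defined by
# figure panels; their adjacency patterns are registered here and may be
# re-pointed with configure_figure_motifs if a different reading is needed.
#   FIG2A -- overrepresented against the fixed-out-degree null (a rare,
#            reciprocity-driven shape; default: mutual dyad with an edge
#            leaving it, 111U);
#   FIG2B -- overrepresented against the Erdős–Rényi null (default: the
#            transitive/feed-forward triple, 030T);
#   FIG2C -- overrepresented against both nulls (default: mutual dyad with a
#            disconnected spectator node, 102).
# ---------------------------------------------------------------------------

_figure_motifs: dict[str, str] = {"FIG2A": "111U", "FIG2B": "030T", "FIG2C": "102"}


def figure_motifs() -> dict[str, str]:
    """Current FIG2A/FIG2B/FIG2C triad-class registration."""
    return dict(_figure_motifs)


def configure_figure_motifs(
    fig2a: str | None = None, fig2b: str | None = None, fig2c: str | None = None
) -> dict[str, str]:
    """Re-register the figure motif constants (each a triad class label)."""
    for key, value in (("FIG2A", fig2a), ("FIG2B", fig2b), ("FIG2C", fig2c)):
        if value is not None:
            _figure_motifs[key] = _check_label(value)
    return figure_motifs()
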