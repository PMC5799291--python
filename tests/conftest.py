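import numpy as np
import pytest

from mircore.annotation_io import (
    LocationClass,
    MirnaGeneAnnotation,
    Orientation,
)
from mircore.network_build import GeneNetwork


def make_network(edges, nodes=()):
    """GeneNetwork from bare (source, target) pairs, empty miRNA labels."""
    return GeneNetwork(
        edges={(u, v): frozenset() for (u, v) in edges},
        nodes=frozenset(nodes),
    )


def random_network(rng: np.random.Generator, n: int, m: int) -> GeneNetwork:
    """Uniform random simple digraph used by oracle-equivalence suites."""
    capacity = n * (n - 1)
    m = min(m, capacity)
    idx = rng.choice(capacity, size=m, replace=False)
    names = [f"V{i:03d}" for i in range(n)]
    edges = set()
    for i in idx:
        u, r = divmod(int(i), n - 1)
        v = r if r < u else r + 1
        edges.add((names[u], names[v]))
    return make_network(edges, nodes=names)


@pytest.fixture
def toy_annotations():
    """G1 hosts m1 targeting {G1, G2, G3}; G2 hosts m2 targeting {G1}."""
    annotations = [
        MirnaGeneAnnotation("pre-m1", "G1", LocationClass.INTRONIC, Orientation.SENSE),
        MirnaGeneAnnotation("pre-m2", "G2", LocationClass.INTRONIC, Orientation.SENSE),
    ]
    mat_map = {"m1": frozenset({"pre-m1"}), "m2": frozenset({"pre-m2"})}
    targets = frozenset({("m1", "G1"), ("m1", "G2"), ("m1", "G3"), ("m2", "G1")})
    return annotations, mat_map, targets


@pytest.fixture
def two_component_network():
    """Edges {A->B, B->A, B->C, C->D, D->C}: SCCs {A,B} and {C,D}."""
    return make_network([("A", "B"), ("B", "A"), ("B", "C"), ("C", "D"), ("D", "C")])
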