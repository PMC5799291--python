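"""Random-graph null models and Monte Carlo hypothesis testing.

Two null models are provided, both matched to an observed network:

* ``erdos_renyi_gnm`` — directed G(n, m): exactly ``m`` loop-free directed
  edges placed uniformly over all ordered node pairs;
* ``fixed_outdegree`` — each node ``k`` keeps its observed number of
  out-edges ``N_k``, and its set of targets is uniform over all
  C(n-1, N_k) subsets of the other nodes.  This is equivalent to
  randomising each hosted miRNA's target list while preserving its length.
  Sampling draws, for each node, the first ``N_k`` entries of a
  Fisher–Yates shuffle of {0, …, n-2} and shifts indices past the source
  node by one so the source is never chosen.

Significance of a graph statistic is assessed with the conventional
add-one Monte Carlo estimator p = (r + 1) / (N + 1), where r of the N
replicate graphs are at least as extreme as the observation.  Its floor at
r = 0 is 1/(N+1) — with the customary N = 10,000 replicates the smallest
reportable p-value is ≈ 9.999e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network_build import GeneNetwork

__all__ = [
    "RandomGraphSpec",
    "MonteCarloResult",
    "MonteCarloStatError",
    "gnm_spec_from_network",
    "fixed_outdegree_spec_from_network",
    "sample_random_graph",
    "sample_gnm",
    "sample_fixed_outdegree",
    "monte_carlo_test",
    "motif_count_statistic",
    "core_size_statistic",
]

_MODELS = ("erdos_renyi_gnm", "fixed_outdegree")


@dataclass(frozen=True)
class RandomGraphSpec:
    """Parameters of one null model, including the seed used to sample it."""

    model: str
    n: int
    m: int | None = None
    out_degrees: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.model == "erdos_renyi_gnm":
            if self.m is None:
                raise ValueError("erdos_renyi_gnm requires an edge count m")
            if not 0 <= self.m <= self.n * (self.n - 1):
                raise ValueError(
                    f"m={self.m} outside [0, n(n-1)={self.n * (self.n - 1)}]"
                )
        else:
            if self.out_degrees is None:
                raise ValueError("fixed_outdegree requires an out-degree vector")
            if len(self.out_degrees) != self.n:
                raise ValueError("out-degree vector length must equal n")
            bad = [d for d in self.out_degrees if not 0 <= d <= self.n - 1]
            if bad:
                raise ValueError(f"out-degrees must lie in [0, n-1]; offending values {bad[:5]}")


@dataclass(frozen=True)
class MonteCarloResult:
    """Observed statistic against its null distribution."""

    observed: float
    replicates: int
    n_extreme: int
    p_value: float
    tail: str

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "replicates": self.replicates,
            "n_extreme": self.n_extreme,
            "p_value": self.p_value,
            "tail": self.tail,
        }


class MonteCarloStatError(RuntimeError):
    """The statistic failed on a replicate graph (index reported)."""


def _node_names(n: int) -> list[str]:
    width = len(str(max(n, 1)))
    return [f"N{i:0{width}d}" for i in range(1, n + 1)]


def gnm_spec_from_network(net: GeneNetwork, seed: int = 0) -> RandomGraphSpec:
    """G(n, m) spec matching the node and edge counts of ``net``."""
    return RandomGraphSpec("erdos_renyi_gnm", n=net.n_nodes, m=net.n_edges, seed=seed)


def fixed_outdegree_spec_from_network(net: GeneNetwork, seed: int = 0) -> RandomGraphSpec:
    """Fixed-out-degree spec matching the out-degree vector of ``net``."""
    outdeg = {g: 0 for g in net.nodes}
    for (u, _v) in net.edges:
        outdeg[u] += 1
    degrees = tuple(outdeg[g] for g in sorted(net.nodes))
    return RandomGraphSpec("fixed_outdegree", n=net.n_nodes, out_degrees=degrees, seed=seed)


def sample_gnm(spec: RandomGraphSpec, rng: np.random.Generator | None = None) -> GeneNetwork:
    """One directed G(n, m) sample: m distinct loop-free edges, uniform."""
    if spec.model != "erdos_renyi_gnm":
        raise ValueError("spec.model must be erdos_renyi_gnm")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, m = spec.n, int(spec.m or 0)
    capacity = n * (n - 1)
    names = _node_names(n)
    if capacity <= 2_000_000:
        chosen = rng.choice(capacity, size=m, replace=False)
    else:
        # Rejection sampling of distinct pair indices stays uniform and avoids
        # materialising all n(n-1) candidates for large n at low density.
        seen: set[int] = set()
        while len(seen) < m:
            for idx in rng.integers(0, capacity, size=m - len(seen)):
                seen.add(int(idx))
        chosen = np.fromiter(seen, dtype=np.int64)
    edges: dict[tuple[str, str], frozenset[str]] = {}
    for idx in chosen:
        u, r = divmod(int(idx), n - 1)
        v = r if r < u else r + 1
        edges[(names[u], names[v])] = frozenset()
    return GeneNetwork(edges=edges, nodes=frozenset(names))


def sample_fixed_outdegree(
    spec: RandomGraphSpec, rng: np.random.Generator | None = None
) -> GeneNetwork:
    """One fixed-out-degree sample via the per-node shuffle construction."""
    if spec.model != "fixed_outdegree":
        raise ValueError("spec.model must be fixed_outdegree")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n
    names = _node_names(n)
    edges: dict[tuple[str, str], frozenset[str]] = {}
    degrees = spec.out_degrees or ()
    for k in range(n):
        nk = degrees[k]
        if nk == 0:
            continue
        # First nk entries of a shuffle of {0,...,n-2}; indices >= k shift by
        # one so node k never targets itself.  Uniform over C(n-1, nk) sets.
        picks = rng.permutation(n - 1)[:nk]
        for l in picks:
            v = int(l) if l < k else int(l) + 1
            edges[(names[k], names[v])] = frozenset()
    return GeneNetwork(edges=edges, nodes=frozenset(names))


def sample_random_graph(spec: RandomGraphSpec, rng: np.random.Generator | None = None) -> GeneNetwork:
    if spec.model == "erdos_renyi_gnm":
        return sample_gnm(spec, rng)
    return sample_fixed_outdegree(spec, rng)


def _replicate_rng(seed: int, j: int) -> np.random.Generator:
    # Counter-based stream: replicate j is reproducible independently of the
    # order in which replicates are generated.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(j,)))


def monte_carlo_test(
    net: GeneNetwork,
    stat: Callable[[GeneNetwork], float],
    spec: RandomGraphSpec,
    replicates: int = 10_000,
    tail: str = "upper",
) -> MonteCarloResult:
    """Monte Carlo p-value of ``stat(net)`` under the null model ``spec``.

    ``tail="upper"`` counts replicates with statistic >= the observed value
    (over-representation), ``tail="lower"`` counts <= (e.g. a core smaller
    than expected at random).  Replicate statistics are streamed, not
    retained; the returned p-value is the add-one estimator and can never
    fall below 1/(replicates+1).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    observed = float(stat(net))
    n_extreme = 0
    for j in range(replicates):
        graph = sample_random_graph(spec, rng=_replicate_rng(spec.seed, j))
        try:
            value = float(stat(graph))
        except Exception as exc:  # noqa: BLE001 - annotate failing replicate
            raise MonteCarloStatError(f"statistic failed on replicate {j}: {exc}") from exc
        if tail == "upper" and value >= observed:
            n_extreme += 1
        elif tail == "lower" and value <= observed:
            n_extreme += 1
    p_value = (n_extreme + 1) / (replicates + 1)
    return MonteCarloResult(observed, replicates, n_extreme, p_value, tail)


def motif_count_statistic(motif: str) -> Callable[[GeneNetwork], float]:
    """Graph statistic: induced count of one triad class."""
    from .motif_census import count_motif

    return lambda net: float(count_motif(net, motif))


def core_size_statistic(net: GeneNetwork) -> float:
    """Graph statistic: number of nodes in the network core."""
    from .core_analysis import extract_core

    return float(len(extract_core(net).core))
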