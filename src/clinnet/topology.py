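"""Egalitarian (uniform-degree) communication networks.

The network conditions place every participant at one node of a connected
k-regular graph, so nobody has more communication power than anyone else.
Graphs are built by degree-preserving randomization of a circulant lattice:
repeated double-edge swaps that reject self-loops and multi-edges, retried
until the result is connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import MissingDataError, ValidationError

#: Reference design: 40 nodes, degree 4.
REFERENCE_N = 40
REFERENCE_K = 4

_SWAPS_PER_EDGE = 10
_MAX_REGEN = 100


@dataclass(frozen=True)
class Topology:
    """A simple connected graph in which every node has degree exactly k."""

    n: int
    k: int
    edges: frozenset[tuple[int, int]]
    _adj: dict[int, frozenset[int]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        adj: dict[int, set[int]] = {v: set() for v in range(self.n)}
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop at node {a}")
            if not (0 <= a < self.n and 0 <= b < self.n):
                raise ValidationError(f"edge ({a},{b}) references unknown node")
            adj[a].add(b)
            adj[b].add(a)
        bad = [v for v, nb in adj.items() if len(nb) != self.k]
        if bad:
            raise ValidationError(f"nodes {bad[:5]} do not have degree {self.k}")
        object.__setattr__(self, "_adj", {v: frozenset(nb) for v, nb in adj.items()})

    def neighbors(self, node: int) -> frozenset[int]:
        try:
            return self._adj[node]
        except KeyError:
            raise MissingDataError(f"node {node} not in topology") from None

    def adjacency_matrix(self) -> np.ndarray:
        mat = np.zeros((self.n, self.n), dtype=float)
        for a, b in self.edges:
            mat[a, b] = mat[b, a] = 1.0
        return mat


def neighbors(topology: Topology, node: int) -> frozenset[int]:
    """Set of the k nodes adjacent to ``node``."""
    return topology.neighbors(node)


def neighbor_mean(topology: Topology, estimates: Mapping[int, float], node: int) -> float:
    """Arithmetic mean of the estimates of ``node``'s neighbors.

    Neighbors missing from ``estimates`` (or mapped to NaN) are excluded;
    this only matters under simulated attrition, where each remaining
    neighbor's most recent response should be supplied instead.
    """
    nbrs = topology.neighbors(node)
    values = [
        float(estimates[nb])
        for nb in nbrs
        if nb in estimates and not np.isnan(estimates[nb])
    ]
    if not values:
        raise MissingDataError(f"no neighbor of node {node} has an available estimate")
    return float(np.mean(values))


def _lattice_edges(n: int, k: int) -> set[tuple[int, int]]:
    """Circulant k-regular lattice; for odd k (n even) adds diameter chords."""
    edges: set[tuple[int, int]] = set()
    for off in range(1, k // 2 + 1):
        for v in range(n):
            a, b = v, (v + off) % n
            edges.add((min(a, b), max(a, b)))
    if k % 2 == 1:
        for v in range(n // 2):
            edges.add((v, v + n // 2))
    return edges


def _rewire(edges: set[tuple[int, int]], rng: np.random.Generator) -> set[tuple[int, int]]:
    """Attempt 10 double-edge swaps per edge, rejecting loops/multi-edges."""
    edge_list = list(edges)
    edge_set = set(edges)
    m = len(edge_list)
    for _ in range(_SWAPS_PER_EDGE * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed replacement: (a,c) and (b,d)
        if a == c or b == d:
            continue
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
    return edge_set


def make_egalitarian_network(n: int, k: int, seed: int) -> Topology:
    """Build a connected k-regular graph on n nodes, deterministically per seed.

    Starts from a k-regular lattice and randomizes it with double-edge
    swaps; regenerates (up to 100 times) if the swap sequence disconnects
    the graph.
    """
    if k < 1 or n < k + 1:
        raise ValidationError(f"no simple {k}-regular graph on {n} nodes (need n >= k+1)")
    if (n * k) % 2 != 0:
        raise ValidationError(f"n*k must be even, got n={n}, k={k}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, n, k)))
    lattice = _lattice_edges(n, k)
    for _ in range(_MAX_REGEN):
        edges = _rewire(set(lattice), rng)
        graph = nx.Graph(edges)
        graph.add_nodes_from(range(n))
        if nx.is_connected(graph):
            return Topology(n=n, k=k, edges=frozenset(edges))
    raise RuntimeError(f"failed to draw a connected {k}-regular graph on {n} nodes")


def write_edgelist(topology: Topology, path: str | Path) -> None:
    """Serialize as two 0-based node ids per line, whitespace-separated."""
    lines = [f"{a} {b}" for a, b in sorted(topology.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> Topology:
    edges: set[tuple[int, int]] = set()
    nodes: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"line {lineno}: expected two node ids, got {line!r}")
        a, b = (int(p) for p in parts)
        edges.add((min(a, b), max(a, b)))
        nodes.update((a, b))
    if not edges:
        raise MissingDataError(f"{path}: no edges")
    n = max(nodes) + 1
    degrees = {v: 0 for v in range(n)}
    for a, b in edges:
        degrees[a] += 1
        degrees[b] += 1
    k = degrees[next(iter(nodes))]
    return Topology(n=n, k=k, edges=frozenset(edges))
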