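"""Directed social networks for opinion-dynamics simulations.

An edge (a, b) means agent ``a``'s expressed opinion is visible to agent
``b`` — in social-media terms, b follows a without a necessarily following
back. Networks are static over a simulation run; the entire generated graph
is used as-is, including any disconnected subnetworks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

NETWORK_KINDS = ("erdos_renyi", "barabasi_albert", "scale_free", "complete")


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed influence graph on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of agents.
    edges
        Ordered (source, target) pairs; no self-loops.
    kind
        Generator family the network came from (or "complete").
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    kind: str = "erdos_renyi"

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-loop ({a}, {a}) not allowed")
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError(f"edge ({a}, {b}) out of range for n={self.n_nodes}")

    def in_neighbors(self, i: int) -> set[int]:
        """Agents whose expressed opinions agent ``i`` can see."""
        if not (0 <= i < self.n_nodes):
            raise ValueError(f"node id {i} out of range for n={self.n_nodes}")
        return {a for (a, b) in self.edges if b == i}

    def adjacency(self) -> np.ndarray:
        """Boolean matrix A with A[j, i] True iff edge (j, i) exists."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges:
            src, dst = zip(*self.edges)
            a[list(src), list(dst)] = True
        return a


def in_neighbors(net: DirectedNetwork, i: int) -> set[int]:
    """Functional alias for :meth:`DirectedNetwork.in_neighbors`."""
    return net.in_neighbors(i)


def _seed_int(seed: int, label: str) -> int:
    # stable sub-seed below 2**31 so third-party generators accept it
    # (zlib.crc32 is process-stable, unlike hash())
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    return int(ss.generate_state(1)[0] % 2**31)


def generate_network(kind: str, n: int, k: float, seed: int) -> DirectedNetwork:
    """Build a directed network with ``n`` nodes and about ``k`` links per node.

    ``erdos_renyi`` places each ordered pair independently with probability
    k/(n-1), so expected in-degree and out-degree both equal k.
    ``barabasi_albert`` grows an undirected preferential-attachment graph with
    attachment count round(k/2) and symmetrizes every edge to two directed
    edges (mean total degree ~ k). ``scale_free`` uses a directed
    preferential-attachment growth process, reduced to a simple symmetrized
    digraph. ``complete`` contains every ordered pair.

    Deterministic for fixed (kind, n, k, seed).
    """
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind {kind!r}; choose from {NETWORK_KINDS}")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 <= k <= n - 1):
        raise ValueError(f"k={k} must be in [0, n-1]")

    if kind == "complete":
        edges = {(a, b) for a in range(n) for b in range(n) if a != b}
    elif kind == "erdos_renyi":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        p = k / (n - 1)
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        src, dst = np.nonzero(mask)
        edges = set(zip(src.tolist(), dst.tolist()))
    elif kind == "barabasi_albert":
        m = max(1, round(k / 2))
        g = nx.barabasi_albert_graph(n, m, seed=_seed_int(seed, "ba"))
        edges = {(a, b) for a, b in g.edges()} | {(b, a) for a, b in g.edges()}
    else:  # scale_free
        g = nx.scale_free_graph(n, seed=_seed_int(seed, "sf"))
        und = {(min(a, b), max(a, b)) for a, b in g.edges() if a != b}
        edges = {(a, b) for a, b in und} | {(b, a) for a, b in und}
    return DirectedNetwork(n_nodes=n, edges=frozenset(edges), kind=kind)


def symmetrized(net: DirectedNetwork) -> DirectedNetwork:
    """Undirected variant: every edge is made bidirectional."""
    edges = set(net.edges) | {(b, a) for (a, b) in net.edges}
    return DirectedNetwork(net.n_nodes, frozenset(edges), net.kind)


def write_network(net: DirectedNetwork, path: str | Path) -> None:
    """Serialize to an edge-list text file or GraphML (by .graphml suffix).

    The edge-list format is a header line ``n=<n_nodes>`` followed by one
    ``src dst`` pair per line.
    """
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.DiGraph()
        g.add_nodes_from(range(net.n_nodes))
        g.add_edges_from(net.edges)
        g.graph["kind"] = net.kind
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        fh.write(f"n={net.n_nodes}\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a} {b}\n")


def read_network(path: str | Path, kind: str = "erdos_renyi") -> DirectedNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path, node_type=int)
        edges = frozenset((int(a), int(b)) for a, b in g.edges())
        return DirectedNetwork(
            g.number_of_nodes(), edges, g.graph.get("kind", kind)
        )
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("n="):
            raise ValueError(f"malformed header {header!r}; expected 'n=<count>'")
        n = int(header[2:])
        edges = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}")
            edges.add((int(parts[0]), int(parts[1])))
    return DirectedNetwork(n, frozenset(edges), kind)
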