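"""Minimum-spanning-tree backbone extraction and tree metrics.

In weighted functional-connectivity analysis the "minimum spanning tree" is,
by convention, the spanning tree that retains the *strongest* coherence edges
(equivalently, the minimum spanning tree of the reciprocal weights).  The tree
is a loop-free backbone of N-1 edges whose topology metrics — diameter, degree
divergence (kappa), leaf fraction, nodal degree and betweenness — are
insensitive to uniform rescaling of connectivity strength, which is the point
of using it for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SpanningTree",
    "GlobalMetrics",
    "NodalMetrics",
    "maximum_spanning_tree",
    "mean_edge_weight",
    "diameter",
    "kappa",
    "leaf_fraction",
    "degree_vector",
    "betweenness_vector",
    "tree_overlap",
    "compute_global_metrics",
    "compute_nodal_metrics",
]


@dataclass
class SpanningTree:
    """A spanning tree over an ordered node set, edge weights retained.

    ``edges`` holds ``(i, j, weight)`` with ``i < j`` indexing into
    ``node_ids``; there are exactly ``N - 1`` of them.
    """

    node_ids: list[str]
    edges: list[tuple[int, int, float]]
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if n < 2:
            raise ValueError("a spanning tree needs at least 2 nodes")
        if len(self.edges) != n - 1:
            raise ValueError(
                f"spanning tree on {n} nodes must have {n - 1} edges, "
                f"got {len(self.edges)}"
            )
        g = self.graph
        if not nx.is_connected(g):
            raise ValueError("edge list does not connect all nodes")
        # connected + N-1 edges => acyclic, no further check needed

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_nodes))
            for i, j, w in self.edges:
                g.add_edge(int(i), int(j), weight=float(w))
            self._graph = g
        return self._graph

    @classmethod
    def from_edges(
        cls,
        node_ids: Sequence[str],
        edges: Sequence[tuple[int, int, float]],
    ) -> "SpanningTree":
        norm = []
        for i, j, w in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError("self-loop in edge list")
            if i > j:
                i, j = j, i
            norm.append((i, j, float(w)))
        return cls(node_ids=list(node_ids), edges=norm)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for i, j, _ in self.edges)


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-tree summary metrics."""

    strength: float          # mean MST edge weight (coherence units)
    diameter_edges: int      # longest path, counted in edges
    diameter_norm: float     # diameter_edges / (N - 1)
    kappa: float             # <degree^2> / <degree>, degree divergence
    leaf_fraction: float     # degree-1 nodes / N


@dataclass(frozen=True)
class NodalMetrics:
    node_ids: list[str]
    degree: np.ndarray       # per-node edge counts
    betweenness: np.ndarray  # normalized, in [0, 1]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(
    weights: np.ndarray, node_ids: Sequence[str] | None = None
) -> SpanningTree:
    """Maximum-weight spanning tree of a symmetric coherence matrix.

    Kruskal's algorithm with a deterministic tie-break: edges sorted by
    weight descending, then by (i, j) lexicographically ascending.  Requires
    a fully connected weighted graph (all off-diagonal weights > 0).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.allclose(w, w.T, atol=1e-12, rtol=0.0):
        raise ValueError("weight matrix must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    if np.any(vals <= 0.0):
        raise ValueError(
            "all off-diagonal weights must be positive (disconnected graph)"
        )
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(n)]
    elif len(node_ids) != n:
        raise ValueError("node_ids length does not match matrix size")

    order = sorted(range(len(vals)), key=lambda k: (-vals[k], iu[k], ju[k]))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(vals[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(node_ids=list(node_ids), edges=edges)


def mean_edge_weight(tree: SpanningTree) -> float:
    """Connectivity strength: arithmetic mean of the N-1 MST edge weights."""
    return float(np.mean([w for _, _, w in tree.edges]))


def diameter(tree: SpanningTree) -> tuple[int, float]:
    """Longest unweighted path between any two nodes.

    Returns (edge count, edge count / (N - 1)).
    """
    d = nx.diameter(tree.graph)
    return int(d), float(d) / (tree.n_nodes - 1)


def degree_vector(tree: SpanningTree) -> np.ndarray:
    deg = np.zeros(tree.n_nodes, dtype=int)
    for i, j, _ in tree.edges:
        deg[i] += 1
        deg[j] += 1
    return deg


def kappa(tree: SpanningTree) -> float:
    """Degree divergence <k^2>/<k>; high values mean dominant hubs."""
    deg = degree_vector(tree).astype(float)
    return float(np.mean(deg**2) / np.mean(deg))


def leaf_fraction(tree: SpanningTree) -> float:
    """Fraction of nodes with exactly one edge."""
    deg = degree_vector(tree)
    return float(np.count_nonzero(deg == 1) / tree.n_nodes)


def betweenness_vector(tree: SpanningTree) -> np.ndarray:
    """Normalized betweenness: fraction of the (N-1)(N-2)/2 node pairs
    (excluding the node itself) whose unique tree path passes through it.
    Ranges from 0 (leaf) to 1 (hub of a star)."""
    n = tree.n_nodes
    if n < 3:
        return np.zeros(n)
    bc = nx.betweenness_centrality(tree.graph, normalized=True, weight=None)
    return np.array([bc[i] for i in range(n)])


def tree_overlap(tree_a: SpanningTree, tree_b: SpanningTree) -> float:
    """Fraction of edges two spanning trees share; 0 (disjoint) to 1 (equal)."""
    if tree_a.node_ids != tree_b.node_ids:
        raise ValueError("trees must be defined on the identical node set")
    shared = tree_a.edge_set() & tree_b.edge_set()
    return len(shared) / (tree_a.n_nodes - 1)


def compute_global_metrics(tree: SpanningTree) -> GlobalMetrics:
    d_edges, d_norm = diameter(tree)
    return GlobalMetrics(
        strength=mean_edge_weight(tree),
        diameter_edges=d_edges,
        diameter_norm=d_norm,
        kappa=kappa(tree),
        leaf_fraction=leaf_fraction(tree),
    )


def compute_nodal_metrics(tree: SpanningTree) -> NodalMetrics:
    return NodalMetrics(
        node_ids=list(tree.node_ids),
        degree=degree_vector(tree),
        betweenness=betweenness_vector(tree),
    )
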