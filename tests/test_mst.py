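"""Spanning-tree extraction and tree metrics.

The key oracle is exhaustive Prüfer-sequence enumeration of all n^(n-2)
labelled spanning trees for small n, against which the Kruskal construction
must be exact; metric formulas are checked against closed forms for star and
path topologies.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import path_tree, random_symmetric_matrix, star_tree
from mstnet.mst import (SpanningTree, betweenness_vector,
                        compute_global_metrics, degree_vector, diameter,
                        kappa, leaf_fraction, maximum_spanning_tree,
                        mean_edge_weight, tree_overlap)

# ---------------------------------------------------------------- oracles


def prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence into the edge list of its labelled tree."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        leaf = min(i for i in range(n) if degree[i] == 1)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[leaf] -= 1
        degree[v] -= 1
    u, w = [i for i in range(n) if degree[i] == 1]
    edges.append((u, w))
    return edges


_TREE_CACHE: dict[int, np.ndarray] = {}


def all_tree_edge_indices(n: int) -> np.ndarray:
    """(n^(n-2), n-1) array of flat upper-triangle edge indices, one row per
    labelled spanning tree of K_n."""
    if n not in _TREE_CACHE:
        iu, ju = np.triu_indices(n, k=1)
        flat = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
        rows = []
        for seq in itertools.product(range(n), repeat=max(n - 2, 0)):
            rows.append([flat[e] for e in prufer_to_edges(seq, n)])
        _TREE_CACHE[n] = np.array(rows, dtype=int)
    return _TREE_CACHE[n]


def brute_force_max_tree_weight(w: np.ndarray) -> float:
    n = w.shape[0]
    if n == 2:
        return float(w[0, 1])
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    return float(vals[all_tree_edge_indices(n)].sum(axis=1).max())


def brute_force_betweenness(tree: SpanningTree) -> np.ndarray:
    """Path-enumeration betweenness: fraction of node pairs whose unique
    path passes through each node."""
    n = tree.n_nodes
    g = tree.graph
    counts = np.zeros(n)
    for y, z in itertools.combinations(range(n), 2):
        path = nx.shortest_path(g, y, z)
        for x in path[1:-1]:
            counts[x] += 1
    return counts / (((n - 1) * (n - 2)) / 2)


# ----------------------------------------------------------------- tests


def test_max_tree_matches_prufer_enumeration(rng):
    """Kruskal tree weight equals the exhaustive maximum over all labelled
    spanning trees, for 200 random matrices with n <= 7."""
    for _ in range(200):
        n = int(rng.integers(2, 8))
        w = random_symmetric_matrix(n, rng)
        tree = maximum_spanning_tree(w)
        total = sum(e[2] for e in tree.edges)
        assert total == pytest.approx(brute_force_max_tree_weight(w), abs=1e-10)


def test_max_tree_matches_networkx(rng):
    for _ in range(10):
        n = 40
        w = random_symmetric_matrix(n, rng)
        ours = sum(e[2] for e in maximum_spanning_tree(w).edges)
        g = nx.from_numpy_array(w)
        theirs = sum(
            d["weight"] for _, _, d in nx.maximum_spanning_tree(g).edges(data=True)
        )
        assert ours == pytest.approx(theirs, rel=1e-12)


def test_three_node_example():
    """ab=0.9, ac=0.5, bc=0.8: the strongest backbone is {ab, bc}."""
    w = np.array([[0, 0.9, 0.5], [0.9, 0, 0.8], [0.5, 0.8, 0]])
    tree = maximum_spanning_tree(w)
    assert tree.edge_set() == {(0, 1), (1, 2)}
    assert sum(e[2] for e in tree.edges) == pytest.approx(1.7)


def test_two_nodes_single_edge():
    tree = maximum_spanning_tree(np.array([[0.0, 0.4], [0.4, 0.0]]))
    assert tree.edges == [(0, 1, 0.4)]
    assert diameter(tree) == (1, 1.0)
    assert leaf_fraction(tree) == 1.0
    assert kappa(tree) == 1.0


@pytest.mark.parametrize("bad", [
    np.array([[0.0, 1.0], [0.5, 0.0]]),           # asymmetric
    np.array([[0.0, 0.0], [0.0, 0.0]]),           # zero weight => disconnected
    np.zeros((1, 1)),                             # single node
])
def test_max_tree_rejects_invalid(bad):
    with pytest.raises(ValueError):
        maximum_spanning_tree(bad)


def test_mean_edge_weight_examples():
    t = SpanningTree.from_edges(["a", "b", "c"], [(0, 1, 0.9), (1, 2, 0.8)])
    assert mean_edge_weight(t) == pytest.approx(0.85)
    assert mean_edge_weight(star_tree(6, weight=0.3)) == pytest.approx(0.3)


@pytest.mark.parametrize("n", range(3, 51))
def test_closed_forms_star_and_path(n):
    """kappa(star)=N/2, kappa(path)=(4N-6)/(2N-2), leaf_fraction(star)=(N-1)/N,
    diameter_norm(path)=1."""
    star, path = star_tree(n), path_tree(n)
    assert kappa(star) == pytest.approx(n / 2)
    assert kappa(path) == pytest.approx((4 * n - 6) / (2 * n - 2))
    assert leaf_fraction(star) == pytest.approx((n - 1) / n)
    assert diameter(path)[1] == pytest.approx(1.0)
    assert diameter(star) == (2, 2 / (n - 1))


def test_path5_metrics(path5):
    assert diameter(path5) == (4, 1.0)
    assert kappa(path5) == pytest.approx(1.75)
    assert leaf_fraction(path5) == pytest.approx(0.4)
    mid = betweenness_vector(path5)[2]
    assert mid == pytest.approx(4 / 6)


def test_star_betweenness_range(star5):
    bc = betweenness_vector(star5)
    assert bc[0] == pytest.approx(1.0)  # hub: every pair passes through it
    assert np.all(bc[1:] == 0.0)        # leaves


def test_betweenness_matches_path_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(4, 10))
        tree = maximum_spanning_tree(random_symmetric_matrix(n, rng))
        np.testing.assert_allclose(
            betweenness_vector(tree), brute_force_betweenness(tree), atol=1e-12
        )


def test_degree_sum_and_leaf_betweenness(rng):
    tree = maximum_spanning_tree(random_symmetric_matrix(30, rng))
    deg = degree_vector(tree)
    assert deg.sum() == 2 * (30 - 1)
    bc = betweenness_vector(tree)
    assert np.all(bc[deg == 1] == 0.0)


def test_strength_invariance_under_scaling(rng):
    """Multiplying the matrix by c > 0 leaves the selected edge set and all
    topology metrics bit-identical and scales strength by exactly c."""
    w = random_symmetric_matrix(25, rng)
    for c in (0.5, 2.0, 17.3):
        t1, t2 = maximum_spanning_tree(w), maximum_spanning_tree(c * w)
        assert t1.edge_set() == t2.edge_set()
        g1, g2 = compute_global_metrics(t1), compute_global_metrics(t2)
        assert g2.strength == pytest.approx(c * g1.strength, rel=1e-12)
        assert g2.diameter_edges == g1.diameter_edges
        assert g2.kappa == g1.kappa
        assert g2.leaf_fraction == g1.leaf_fraction
        np.testing.assert_array_equal(degree_vector(t1), degree_vector(t2))
        np.testing.assert_array_equal(
            betweenness_vector(t1), betweenness_vector(t2)
        )


def test_tree_overlap():
    ids = ["a", "b", "c", "d"]
    a = SpanningTree.from_edges(ids, [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
    b = SpanningTree.from_edges(ids, [(0, 2, 1), (0, 3, 1), (1, 3, 1)])
    c = SpanningTree.from_edges(ids, [(0, 1, 1), (1, 2, 1), (1, 3, 1)])
    assert tree_overlap(a, a) == 1.0
    assert tree_overlap(a, b) == 0.0  # edge-disjoint spanning trees
    assert tree_overlap(a, c) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        tree_overlap(a, SpanningTree.from_edges(["x", "y"], [(0, 1, 1)]))


def test_spanning_tree_validation():
    with pytest.raises(ValueError):  # cycle (4 edges on 4 nodes)
        SpanningTree.from_edges(["a", "b", "c", "d"],
                                [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1)])
    with pytest.raises(ValueError):  # disconnected
        SpanningTree.from_edges(["a", "b", "c", "d"], [(0, 1, 1), (0, 1, 2), (2, 3, 1)])
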