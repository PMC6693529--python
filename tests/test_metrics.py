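"""Graph-theory metrics against hand cases and brute-force oracles."""

import itertools

import numpy as np
import pytest

from connrepro import compute_global_metrics, compute_node_metrics, shortest_path_lengths
from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def floyd_warshall(W):
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return D


def enumerate_shortest_paths(W, s, t):
    """All simple shortest paths s -> t by exhaustive enumeration."""
    n = W.shape[0]
    best = np.inf
    paths = []
    stack = [(s, (s,), 0.0)]
    while stack:
        v, path, length = stack.pop()
        if length > best * (1 + 1e-12):
            continue
        if v == t:
            if length < best * (1 - 1e-12):
                best, paths = length, [path]
            elif abs(length - best) <= best * 1e-12:
                paths.append(path)
            continue
        for w in range(n):
            if W[v, w] > 0 and w not in path:
                stack.append((w, path + (w,), length + 1.0 / W[v, w]))
    return best, paths


def brute_betweenness(W):
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        best, paths = enumerate_shortest_paths(W, s, t)
        if not np.isfinite(best) or not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    return bc / 2.0


def brute_clustering(W):
    n = W.shape[0]
    mx = W.max()
    Wh = np.where(W > 0, (W / mx) ** (1 / 3), 0.0)
    C = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i])[0]
        if nbrs.size < 2:
            continue
        total = 0.0
        for j, h in itertools.permutations(nbrs, 2):
            total += Wh[i, j] * Wh[j, h] * Wh[h, i]
        C[i] = total / (nbrs.size * (nbrs.size - 1))
    return C


def brute_global_efficiency(W):
    D = floyd_warshall(W)
    n = W.shape[0]
    acc = 0.0
    for i, j in itertools.permutations(range(n), 2):
        if np.isfinite(D[i, j]) and D[i, j] > 0:
            acc += 1.0 / D[i, j]
    return acc / (n * (n - 1))


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


def path_graph3():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    return W


def test_path_graph_distances():
    D = shortest_path_lengths(path_graph3())
    assert D[0, 2] == 2.0
    assert D[0, 0] == 0.0


def test_disconnected_pair_is_infinite():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 1.0
    D = shortest_path_lengths(W)
    assert np.isinf(D[0, 2])
    assert np.isinf(D[2, 3])


def test_negative_weight_rejected():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = -1.0
    with pytest.raises(ValueError):
        shortest_path_lengths(W)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dijkstra_matches_floyd_warshall(seed):
    rng = np.random.default_rng(seed)
    W = random_weighted_graph(7, 0.5, rng)
    assert np.allclose(shortest_path_lengths(W), floyd_warshall(W), equal_nan=True)


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------


def test_complete_k4_closed_form():
    W = np.ones((4, 4)) - np.eye(4)
    tbl = compute_node_metrics(W)
    assert np.allclose(tbl["clustering"], 1.0)
    assert np.allclose(tbl["betweenness"], 0.0)
    assert np.array_equal(tbl["degree"], [3, 3, 3, 3])


def test_star_graph_closed_form():
    # Hub 0 with 4 unit-weight leaves: hub betweenness = C(4,2) = 6 in the
    # unordered-pair convention; leaf clustering 0.
    W = np.zeros((5, 5))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    tbl = compute_node_metrics(W)
    assert tbl["betweenness"].iloc[0] == 6.0
    assert np.allclose(tbl["betweenness"].iloc[1:], 0.0)
    assert np.allclose(tbl["clustering"].iloc[1:], 0.0)
    assert tbl["degree"].iloc[0] == 4


@pytest.mark.parametrize("seed", [3, 11])
def test_node_metrics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    W = random_weighted_graph(8, 0.5, rng)
    tbl = compute_node_metrics(W)
    assert np.allclose(tbl["betweenness"], brute_betweenness(W), atol=1e-9)
    assert np.allclose(tbl["clustering"], brute_clustering(W), atol=1e-9)
    # local efficiency: GE of the neighbourhood subgraph via the FW oracle
    for i in range(8):
        nbrs = np.nonzero(W[i])[0]
        expected = brute_global_efficiency(W[np.ix_(nbrs, nbrs)]) if nbrs.size >= 2 else 0.0
        assert tbl["local_efficiency"].iloc[i] == pytest.approx(expected, abs=1e-9)
    assert np.array_equal(tbl["degree"], (W > 0).sum(axis=1))
    assert np.allclose(tbl["strength"], W.sum(axis=1))


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------


def test_complete_graph_global():
    for n in (3, 5):
        W = np.ones((n, n)) - np.eye(n)
        rec = compute_global_metrics(W)
        assert rec.global_efficiency == pytest.approx(1.0)
        assert rec.characteristic_path_length == pytest.approx(1.0)


def test_path_graph_global_hand_enumeration():
    # Ordered-pair inverse lengths: {1, 1, 1/2, 1, 1, 1/2} -> mean 5/6.
    rec = compute_global_metrics(path_graph3())
    assert rec.global_efficiency == pytest.approx(5.0 / 6.0)
    assert rec.characteristic_path_length == pytest.approx((1 + 1 + 2 + 1 + 1 + 2) / 6)


def test_two_disjoint_edges_global_hand_enumeration():
    # 12 ordered pairs, 4 reachable at distance 1: GE = 4/12, CPL = 1.
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    rec = compute_global_metrics(W)
    assert rec.global_efficiency == pytest.approx(1.0 / 3.0)
    assert rec.characteristic_path_length == pytest.approx(1.0)


def test_edgeless_graph_ge_zero_cpl_nan():
    W = np.zeros((5, 5))
    with pytest.warns(UserWarning):
        rec = compute_global_metrics(W)
    assert rec.global_efficiency == 0.0
    assert np.isnan(rec.characteristic_path_length)


def test_weight_scaling_behaviour():
    """Scaling weights by c leaves degree, scales strength by c, CPL by 1/c,
    GE by c; on max-1-normalised graphs everything is scale-free."""
    rng = np.random.default_rng(5)
    W = random_weighted_graph(8, 0.6, rng)
    c = 3.7
    t1, t2 = compute_node_metrics(W), compute_node_metrics(c * W)
    assert np.array_equal(t1["degree"], t2["degree"])
    assert np.allclose(t2["strength"], c * t1["strength"])
    assert np.allclose(t2["clustering"], t1["clustering"])  # pre-scaled by max
    g1, g2 = compute_global_metrics(W), compute_global_metrics(c * W)
    assert g2.characteristic_path_length == pytest.approx(g1.characteristic_path_length / c)
    assert g2.global_efficiency == pytest.approx(c * g1.global_efficiency)
    # max-1 normalisation makes the graph scale-free
    Wn = W / W.max()
    gn1 = compute_global_metrics(Wn)
    gn2 = compute_global_metrics((c * W) / (c * W).max())
    assert gn1 == gn2
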