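"""Weighted graph-theoretical metrics for brain networks.

Conventions (standard in the weighted-connectome literature):

* Edge weights are connection strengths; the *length* of an edge for
  path-based metrics is the reciprocal of its weight, so stronger
  connections are shorter.
* *Degree* is the binary degree of the weighted graph's support; *strength*
  (sum of incident weights) is computed alongside but reported separately.
* *Clustering* is the Onnela weighted clustering coefficient: the geometric
  mean of triangle weights, with weights pre-scaled by the maximum weight of
  the graph.
* *Local efficiency* of node i is the global efficiency of the subgraph
  induced on i's neighbours.
* *Betweenness* is unnormalised Brandes betweenness on 1/weight lengths,
  with fractional credit for tied shortest paths; the value reported is the
  undirected (unordered-pair) count, i.e. the ordered-pair sum halved.
* *Global efficiency* is the mean over ordered node pairs of the inverse
  shortest-path length (0 for unreachable pairs); the *characteristic path
  length* is the mean shortest-path length over reachable ordered pairs.

All metrics are implemented directly in this module (they are the quantities
under study, cross-checked against brute-force oracles in the test suite)
rather than delegated to a graph toolbox.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .containers import matrix_sparsity, validate_adjacency

__all__ = [
    "GlobalMetricsRecord",
    "shortest_path_lengths",
    "global_efficiency",
    "compute_global_metrics",
    "compute_node_metrics",
]


@dataclass(frozen=True)
class GlobalMetricsRecord:
    """Whole-graph summary: global efficiency, characteristic path length, sparsity."""

    global_efficiency: float
    characteristic_path_length: float
    sparsity: float


def shortest_path_lengths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths on edge lengths 1/weight.

    Parameters
    ----------
    adjacency:
        Symmetric non-negative weight matrix with zero diagonal.

    Returns
    -------
    ndarray
        N x N matrix of path lengths; ``inf`` for unreachable pairs, 0 on
        the diagonal.
    """
    W = np.asarray(adjacency, dtype=float)
    if W.min(initial=0.0) < 0:
        raise ValueError("negative edge weights are not allowed")
    n = W.shape[0]
    rows, cols = np.nonzero(np.triu(W, k=1))
    lengths = 1.0 / W[rows, cols]
    graph = csr_array(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return dijkstra(graph, directed=False)


def _efficiency_from_lengths(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(D)
    finite = np.isfinite(D) & (D > 0)
    inv[finite] = 1.0 / D[finite]
    return float(inv[off].mean())


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    return _efficiency_from_lengths(shortest_path_lengths(adjacency))


def compute_global_metrics(adjacency: np.ndarray) -> GlobalMetricsRecord:
    """Global efficiency, characteristic path length and sparsity of a graph.

    An edgeless graph has efficiency 0 and an undefined characteristic path
    length, reported as NaN with a warning.
    """
    W = np.asarray(adjacency, dtype=float)
    validate_adjacency(W, name="adjacency")
    D = shortest_path_lengths(W)
    ge = _efficiency_from_lengths(D)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(D) & off
    if reachable.any():
        cpl = float(D[reachable].mean())
    else:
        warnings.warn("graph has no edges: characteristic path length undefined (NaN)")
        cpl = float("nan")
    return GlobalMetricsRecord(
        global_efficiency=ge,
        characteristic_path_length=cpl,
        sparsity=matrix_sparsity(W),
    )


def _onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity per node."""
    n = W.shape[0]
    k = (W > 0).sum(axis=1)
    mx = W.max(initial=0.0)
    if mx <= 0:
        return np.zeros(n)
    Wh = np.cbrt(W / mx)
    cyc = np.diagonal(Wh @ Wh @ Wh)
    denom = k * (k - 1)
    out = np.zeros(n)
    mask = denom > 0
    out[mask] = cyc[mask] / denom[mask]
    return out


def _brandes_betweenness(W: np.ndarray) -> np.ndarray:
    """Weighted betweenness centrality (Brandes), unordered-pair convention."""
    n = W.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        row = W[i]
        for j in np.nonzero(row)[0]:
            adj[i].append((int(j), 1.0 / row[j]))
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        settled = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if settled[v]:
                continue
            settled[v] = True
            order.append(v)
            for w, ell in adj[v]:
                nd = d + ell
                if nd < dist[w]:
                    dist[w] = nd
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (nd, w))
                elif nd == dist[w] and not settled[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    # Each unordered pair is counted from both endpoints.
    return bc / 2.0


def compute_node_metrics(adjacency: np.ndarray, node_labels=None) -> pd.DataFrame:
    """Per-node metric table: degree, strength, clustering, local efficiency,
    betweenness.

    Parameters
    ----------
    adjacency:
        Symmetric non-negative weight matrix with zero diagonal.
    node_labels:
        Optional sequence of node names used as the index.

    Returns
    -------
    DataFrame
        One row per node with columns ``degree``, ``strength``,
        ``clustering``, ``local_efficiency``, ``betweenness``.
    """
    W = np.asarray(adjacency, dtype=float)
    validate_adjacency(W, name="adjacency")
    n = W.shape[0]
    degree = (W > 0).sum(axis=1).astype(int)
    strength = W.sum(axis=1)
    clustering = _onnela_clustering(W)

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i])[0]
        if nbrs.size >= 2:
            sub = W[np.ix_(nbrs, nbrs)]
            local_eff[i] = global_efficiency(sub)

    betweenness = _brandes_betweenness(W)

    index = pd.Index(node_labels if node_labels is not None else range(n), name="node")
    return pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "clustering": clustering,
            "local_efficiency": local_eff,
            "betweenness": betweenness,
        },
        index=index,
    )
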