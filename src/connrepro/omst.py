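"""Data-driven topology selection and multi-metric graph integration.

Two algorithms live here:

**Orthogonal Minimal Spanning Trees (OMST).** Successive minimal spanning
trees are extracted from a weighted graph under edge length 1/weight, each
round restricted to edges unused by previous rounds ("orthogonal"). The
union of the first m trees, U_m, is scored by the objective

    J(m) = GE(U_m) - Cost(U_m)

where GE is the weighted global efficiency of the union and Cost is the
total weight of retained edges divided by the total weight of all input
edges (so Cost is in [0, 1]). The returned topology is U_{m*} at the round
m* maximising J. The result is connected over all non-isolated nodes by
construction and requires no arbitrary threshold: both strong and weak
edges can survive if they help efficiency more than they cost.

**Graph diffusion distance (GDD).** The distance between two graphs on a
common node set is the maximum over diffusion times t of the Frobenius norm
of the difference of their heat kernels exp(-t L), with L = D - W the
combinatorial graph Laplacian. A linear combination of several single-metric
graphs (an *integrated* graph) is chosen by minimising the summed GDD from
the mixture to each input graph over the coefficient simplex.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh

from .containers import upper_triangle, validate_adjacency
from .metrics import global_efficiency

__all__ = [
    "OmstResult",
    "IntegrationResult",
    "omst_filter",
    "graph_diffusion_distance",
    "integrate_metrics",
    "DEFAULT_T_GRID",
]

#: Default diffusion-time grid for the GDD: 20 log-spaced points in [1e-2, 10].
DEFAULT_T_GRID: np.ndarray = np.logspace(-2, 1, 20)


# ---------------------------------------------------------------------------
# OMST
# ---------------------------------------------------------------------------


@dataclass
class OmstResult:
    """Outcome of OMST topological filtering."""

    selected_mask: np.ndarray          # symmetric boolean N x N
    n_rounds_used: int
    objective_trace: List[Tuple[int, float]]   # (round m, GE(U_m) - Cost(U_m))
    sparsity: float


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


def _kruskal_forest(
    edges: Sequence[Tuple[float, int, int]], n_nodes: int, active: Sequence[int]
) -> Tuple[List[Tuple[int, int]], bool]:
    """Minimum spanning forest by Kruskal over the given (length, i, j) edges.

    Edges must be pre-sorted by (length, i, j) so that ties break
    lexicographically and the result is deterministic. Returns the chosen
    edges and whether they span all ``active`` nodes as a single tree.
    """
    uf = _UnionFind(n_nodes)
    chosen: List[Tuple[int, int]] = []
    needed = len(active) - 1
    for _, i, j in edges:
        if uf.union(i, j):
            chosen.append((i, j))
            if len(chosen) == needed:
                break
    spanning = len(chosen) == needed
    return chosen, spanning


def omst_filter(weights: np.ndarray, max_rounds: Optional[int] = None) -> OmstResult:
    """Select a data-driven topology by orthogonal minimal spanning trees.

    Parameters
    ----------
    weights:
        Symmetric non-negative matrix with zero diagonal; edge weights are
        connection strengths (MST edge length is 1/weight, ties broken by
        lexicographic node-pair order).
    max_rounds:
        Optional cap on the number of orthogonal MST rounds; by default the
        iteration continues until the residual graph no longer connects all
        non-isolated nodes.

    Returns
    -------
    OmstResult
        Union of the first m* trees at the objective-maximising round m*.

    Raises
    ------
    ValueError
        If no positive edge exists or the non-isolated nodes are not
        connected (no spanning tree exists).
    """
    W = np.asarray(weights, dtype=float)
    validate_adjacency(W, name="weights")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pos = W[iu, ju] > 0
    if not pos.any():
        raise ValueError("input graph has no positive edges")
    total_weight = float(W[iu, ju][pos].sum())
    active = sorted(set(iu[pos]) | set(ju[pos]))

    # Residual edge pool, sorted once by (length, i, j); rounds remove edges.
    pool = sorted(
        (1.0 / W[i, j], int(i), int(j))
        for i, j in zip(iu[pos], ju[pos])
    )

    mask = np.zeros((n, n), dtype=bool)
    trace: List[Tuple[int, float]] = []
    masks: List[np.ndarray] = []
    m = 0
    while pool:
        if max_rounds is not None and m >= max_rounds:
            break
        chosen, spanning = _kruskal_forest(pool, n, active)
        if not spanning:
            if m == 0:
                raise ValueError(
                    "input graph is disconnected: no spanning tree over the "
                    "non-isolated nodes exists"
                )
            break
        m += 1
        chosen_set = set(chosen)
        pool = [e for e in pool if (e[1], e[2]) not in chosen_set]
        for i, j in chosen:
            mask[i, j] = mask[j, i] = True
        union = np.where(mask, W, 0.0)
        ge = global_efficiency(union)
        cost = float(upper_triangle(union).sum()) / total_weight
        trace.append((m, ge - cost))
        masks.append(mask.copy())

    objectives = np.array([j for _, j in trace])
    m_star = int(np.argmax(objectives)) + 1
    best = masks[m_star - 1]
    return OmstResult(
        selected_mask=best,
        n_rounds_used=m_star,
        objective_trace=trace,
        sparsity=float(np.count_nonzero(upper_triangle(best))) / (n * (n - 1) // 2),
    )


# ---------------------------------------------------------------------------
# Graph diffusion distance
# ---------------------------------------------------------------------------


class _HeatProfile:
    """Eigendecomposition of a graph Laplacian, pre-evaluated on a time grid.

    Enables the Frobenius distance between heat kernels of two graphs via
    the trace identity

        ||K_A(t) - K_B(t)||_F^2
            = sum_p e^{-2 t a_p} + sum_q e^{-2 t b_q}
              - 2 sum_{pq} e^{-t a_p} e^{-t b_q} (u_p . v_q)^2

    without forming the kernels, which makes repeated distance evaluations
    against fixed references cheap.
    """

    def __init__(self, W: np.ndarray, t_grid: np.ndarray) -> None:
        W = np.asarray(W, dtype=float)
        L = np.diag(W.sum(axis=1)) - W
        vals, vecs = eigh(L)
        self.vecs = vecs
        self.expvals = np.exp(-np.outer(vals, t_grid))       # (n, T)
        self.self_sq = (self.expvals ** 2).sum(axis=0)        # (T,)

    def squared_distances(self, other: "_HeatProfile") -> np.ndarray:
        C = (self.vecs.T @ other.vecs) ** 2
        cross = (self.expvals * (C @ other.expvals)).sum(axis=0)
        return np.maximum(self.self_sq + other.self_sq - 2.0 * cross, 0.0)


def graph_diffusion_distance(
    A: np.ndarray, B: np.ndarray, t_grid: Optional[np.ndarray] = None
) -> float:
    """Maximum-over-time Frobenius distance between the heat kernels of two graphs.

    Both matrices must be symmetric, non-negative, zero-diagonal and of the
    same shape. The distance is symmetric in its arguments and zero iff the
    Laplacians coincide on the grid.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    validate_adjacency(A, name="A")
    validate_adjacency(B, name="B")
    grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    pa = _HeatProfile(A, grid)
    pb = _HeatProfile(B, grid)
    return float(np.sqrt(pa.squared_distances(pb).max()))


# ---------------------------------------------------------------------------
# Metric integration on the simplex
# ---------------------------------------------------------------------------


@dataclass
class IntegrationResult:
    """Simplex mixture of metric graphs minimising the summed GDD objective."""

    coefficients: np.ndarray        # non-negative, sums to 1
    integrated_matrix: np.ndarray
    objective_value: float


def _matrix_key(M: np.ndarray) -> int:
    """Stable content key for a matrix, independent of its position in a list."""
    digest = hashlib.blake2b(np.ascontiguousarray(M).tobytes(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def _simplex_grid(k: int, step: float) -> np.ndarray:
    """All points of the k-simplex with coordinates that are multiples of step."""
    levels = int(round(1.0 / step))
    points = []
    for comp in itertools.combinations_with_replacement(range(k), levels):
        alpha = np.zeros(k)
        for idx in comp:
            alpha[idx] += 1
        points.append(alpha / levels)
    return np.array(points)


def integrate_metrics(
    matrices: Sequence[np.ndarray],
    seed: int = 0,
    n_draws: int = 2000,
    grid_step: float = 0.05,
    t_grid: Optional[np.ndarray] = None,
) -> IntegrationResult:
    """Find simplex coefficients mixing metric graphs into an integrated graph.

    The objective is the sum over inputs i of the graph diffusion distance
    between the mixture sum_k alpha_k M_k and M_i; each input is rescaled to
    maximum weight 1 before mixing. For up to three inputs the coefficient
    simplex is searched on a dense grid (step ``grid_step``); for more, a
    seeded Dirichlet random search (``n_draws`` candidates) is followed by a
    best-improvement local refinement over single-coordinate moves.

    The random candidate streams are keyed by a content hash of each input
    matrix, so reordering the inputs permutes every candidate's coordinates
    in lockstep and the optimal objective value is invariant under input
    permutation.
    """
    if len(matrices) < 2:
        raise ValueError("integration requires at least two metric matrices")
    shape = np.asarray(matrices[0]).shape
    rescaled = []
    for idx, M in enumerate(matrices):
        M = np.asarray(M, dtype=float)
        if M.shape != shape:
            raise ValueError("all matrices must share a common shape")
        validate_adjacency(M, name=f"matrix[{idx}]")
        mx = M.max(initial=0.0)
        rescaled.append(M / mx if mx > 0 else M)

    grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    k = len(rescaled)
    profiles = [_HeatProfile(M, grid) for M in rescaled]
    stack = np.stack(rescaled)

    def objective(alpha: np.ndarray) -> float:
        mix = np.tensordot(alpha, stack, axes=1)
        pm = _HeatProfile(mix, grid)
        total = 0.0
        for prof in profiles:
            total += float(np.sqrt(pm.squared_distances(prof).max()))
        return total

    # Canonical coordinate order: by matrix content, so the search path is
    # identical under any permutation of the inputs.
    keys = [_matrix_key(M) for M in rescaled]
    canonical = sorted(range(k), key=lambda idx: keys[idx])

    if k <= 3:
        candidates = _simplex_grid(k, grid_step)
    else:
        gammas = []
        for idx in range(k):
            rng = np.random.default_rng(np.random.SeedSequence([seed, keys[idx]]))
            gammas.append(rng.gamma(1.0, size=n_draws))
        G = np.column_stack(gammas)
        candidates = G / G.sum(axis=1, keepdims=True)
        extra = [np.full(k, 1.0 / k)]
        extra.extend(np.eye(k))
        candidates = np.vstack([candidates, extra])

    values = np.array([objective(a) for a in candidates])
    if not np.all(np.isfinite(values)):
        raise ValueError("integration objective returned a non-finite value")
    best_idx = int(np.argmin(values))
    best_alpha = candidates[best_idx].copy()
    best_value = float(values[best_idx])

    if k > 3:
        for step in (0.1, 0.05, 0.02, 0.01):
            improved = True
            rounds = 0
            while improved and rounds < 25:
                improved = False
                rounds += 1
                for coord in canonical:
                    for sign in (1.0, -1.0):
                        trial = best_alpha.copy()
                        trial[coord] = max(trial[coord] + sign * step, 0.0)
                        total = trial.sum()
                        if total <= 0:
                            continue
                        trial /= total
                        val = objective(trial)
                        if val < best_value - 1e-12:
                            best_alpha, best_value = trial, val
                            improved = True

    integrated = np.tensordot(best_alpha, stack, axes=1)
    return IntegrationResult(
        coefficients=best_alpha,
        integrated_matrix=integrated,
        objective_value=best_value,
    )
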