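"""OMST filtering, graph diffusion distance and metric integration.

The OMST objective maximisation is checked against an exhaustive
round-enumeration oracle that uses networkx's (independent) MST routine and
a Floyd-Warshall-based efficiency; the diffusion distance is checked against
scipy.linalg.expm heat kernels.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from connrepro import (
    graph_diffusion_distance,
    integrate_metrics,
    omst_filter,
    upper_triangle,
)
from connrepro.omst import DEFAULT_T_GRID
from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_global_efficiency(W):
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[W > 0] = 1.0 / W[W > 0]
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    acc = sum(
        1.0 / D[i, j]
        for i, j in itertools.permutations(range(n), 2)
        if np.isfinite(D[i, j]) and D[i, j] > 0
    )
    return acc / (n * (n - 1))


def oracle_omst_objectives(W):
    """GE - Cost at every orthogonal-MST round, via networkx MSTs."""
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    total = upper_triangle(W).sum()
    union = np.zeros_like(W)
    objectives = []
    residual = G.copy()
    while residual.number_of_edges() and nx.is_connected(residual):
        T = nx.minimum_spanning_tree(residual, weight="length")
        for i, j in T.edges:
            union[i, j] = union[j, i] = W[i, j]
            residual.remove_edge(i, j)
        objectives.append(
            oracle_global_efficiency(union) - upper_triangle(union).sum() / total
        )
    return objectives


def heat_kernel(W, t):
    L = np.diag(W.sum(axis=1)) - W
    return expm(-t * L)


def oracle_gdd(A, B, grid=DEFAULT_T_GRID):
    return max(np.linalg.norm(heat_kernel(A, t) - heat_kernel(B, t)) for t in grid)


# ---------------------------------------------------------------------------
# OMST filter
# ---------------------------------------------------------------------------


def test_spanning_tree_input_returned_unchanged():
    # path tree on 5 nodes: 4 of the 10 unique pairs
    W = np.zeros((5, 5))
    for i in range(4):
        W[i, i + 1] = W[i + 1, i] = 0.5 + 0.1 * i
    res = omst_filter(W)
    assert np.array_equal(res.selected_mask, W > 0)
    assert res.n_rounds_used == 1
    assert res.sparsity == pytest.approx(4 / 10)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_objective_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    W = random_weighted_graph(6, 0.9, rng)
    res = omst_filter(W)
    oracle = oracle_omst_objectives(W)
    ours = [j for _, j in res.objective_trace]
    assert len(ours) == len(oracle)
    assert np.allclose(ours, oracle, atol=1e-9)
    assert ours[res.n_rounds_used - 1] == pytest.approx(max(oracle), abs=1e-9)


def test_optimum_dominates_single_mst():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(8, 0.7, rng)
        res = omst_filter(W)
        js = [j for _, j in res.objective_trace]
        assert js[res.n_rounds_used - 1] >= js[0]


def test_selected_subgraph_connected_union_find():
    rng = np.random.default_rng(9)
    W = random_weighted_graph(10, 0.5, rng)
    # knock out one node entirely: result must still span the active nodes
    W[3, :] = W[:, 3] = 0.0
    res = omst_filter(W)
    parent = list(range(10))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(np.triu(res.selected_mask))):
        parent[find(j)] = find(i)
    active = [k for k in range(10) if W[k].any()]
    roots = {find(k) for k in active}
    assert len(roots) == 1
    assert not res.selected_mask[3].any()


def test_disconnected_input_rejected():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    with pytest.raises(ValueError, match="disconnected"):
        omst_filter(W)
    with pytest.raises(ValueError, match="no positive edges"):
        omst_filter(np.zeros((4, 4)))


def test_selected_edges_subset_of_input():
    rng = np.random.default_rng(4)
    W = random_weighted_graph(9, 0.6, rng)
    res = omst_filter(W)
    assert not np.any(res.selected_mask & (W == 0))


# ---------------------------------------------------------------------------
# Graph diffusion distance
# ---------------------------------------------------------------------------


def test_gdd_identity_and_symmetry():
    rng = np.random.default_rng(0)
    A = random_weighted_graph(8, 0.5, rng)
    B = random_weighted_graph(8, 0.5, rng)
    assert graph_diffusion_distance(A, A) == pytest.approx(0.0, abs=1e-7)
    assert graph_diffusion_distance(A, B) == pytest.approx(
        graph_diffusion_distance(B, A), abs=1e-9
    )


def test_gdd_two_node_closed_form():
    """2-node graphs, weights 1 vs 2: K_A - K_B = ((e^{-2t}-e^{-4t})/2) *
    [[1,-1],[-1,1]], so the Frobenius distance is |e^{-2t} - e^{-4t}|,
    maximised near t = ln(2)/2 where it approaches 1/4."""
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    B = np.array([[0.0, 2.0], [2.0, 0.0]])
    expected = max(abs(np.exp(-2 * t) - np.exp(-4 * t)) for t in DEFAULT_T_GRID)
    got = graph_diffusion_distance(A, B)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == pytest.approx(oracle_gdd(A, B), abs=1e-10)
    assert got == pytest.approx(0.25, abs=5e-3)  # grid resolves the peak


@pytest.mark.parametrize("seed", [1, 2])
def test_gdd_matches_expm_oracle(seed):
    rng = np.random.default_rng(seed)
    A = random_weighted_graph(6, 0.6, rng)
    B = random_weighted_graph(6, 0.6, rng)
    assert graph_diffusion_distance(A, B) == pytest.approx(oracle_gdd(A, B), abs=1e-9)


def test_gdd_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        graph_diffusion_distance(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# Metric integration
# ---------------------------------------------------------------------------


def test_identical_inputs_integrate_to_common_matrix():
    rng = np.random.default_rng(2)
    M = random_weighted_graph(7, 0.6, rng)
    M /= M.max()
    res = integrate_metrics([M, M.copy()])
    assert res.objective_value == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(res.integrated_matrix, M)
    assert res.coefficients.sum() == pytest.approx(1.0)
    assert np.all(res.coefficients >= 0)


def test_returned_alpha_beats_random_simplex_points():
    rng = np.random.default_rng(3)
    M = random_weighted_graph(7, 0.6, rng)
    eps = 1e-3 * M
    res = integrate_metrics([M, eps])
    stack = np.stack([M / M.max(), eps / eps.max()])

    def objective(alpha):
        mix = np.tensordot(alpha, stack, axes=1)
        return sum(graph_diffusion_distance(mix, stack[i]) for i in range(2))

    assert res.objective_value == pytest.approx(objective(res.coefficients), abs=1e-7)
    for a in rng.dirichlet(np.ones(2), size=10):
        assert res.objective_value <= objective(a) + 1e-7


def test_nine_metric_mixture_beats_uniform(small_cohort):
    cm = small_cohort.scan_pair("sub-001")[0]
    mats = [cm.matrices[m] for m in sorted(cm.matrices)]
    res = integrate_metrics(mats, seed=0, n_draws=200)
    stack = np.stack([M / M.max() for M in mats])
    uniform = np.full(len(mats), 1.0 / len(mats))
    mix = np.tensordot(uniform, stack, axes=1)
    uniform_obj = sum(graph_diffusion_distance(mix, stack[i]) for i in range(len(mats)))
    assert res.objective_value <= uniform_obj + 1e-9
    assert res.coefficients.sum() == pytest.approx(1.0)


def test_objective_invariant_under_metric_permutation(small_cohort):
    cm = small_cohort.scan_pair("sub-002")[0]
    mats = [cm.matrices[m] for m in ("NS", "FA", "MD", "TV", "TL")]
    res_fwd = integrate_metrics(mats, seed=5, n_draws=100)
    perm = [3, 0, 4, 2, 1]
    res_perm = integrate_metrics([mats[k] for k in perm], seed=5, n_draws=100)
    assert res_perm.objective_value == pytest.approx(res_fwd.objective_value, abs=1e-9)
    assert np.allclose(res_perm.coefficients, res_fwd.coefficients[perm], atol=1e-9)


def test_integrated_support_within_union_of_inputs():
    rng = np.random.default_rng(6)
    A = random_weighted_graph(8, 0.3, rng)
    B = random_weighted_graph(8, 0.3, rng)
    res = integrate_metrics([A, B])
    assert not np.any((res.integrated_matrix > 0) & ~((A > 0) | (B > 0)))


def test_integration_requires_two_matrices():
    with pytest.raises(ValueError):
        integrate_metrics([np.zeros((3, 3))])
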