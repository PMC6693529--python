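"""Test-retest reproducibility statistics for brain graphs.

Implements the comparison layer of the study: cosine similarity of edge
weight vectors (graph similarity), support-agreement fraction (topology
similarity), the absolute fractional difference of edge weights, per-edge
and per-metric intraclass correlation coefficients, a GLM relating edge
reliability to tract attributes, attribute tests for non-reproduced edges,
strongest-edge rankings, and paired comparisons of similarity distributions
with Benjamini-Hochberg FDR correction.

The ICC variant is ICC(A,1): two-way random effects, absolute agreement,
single measurement -- the standard choice for a test-retest design in which
the scan session is a random facet. It is computed from the participant x
scan ANOVA decomposition and may be negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .containers import ConnectivityMatrixSet, METRICS, upper_triangle
from .schemes import BrainGraph

__all__ = [
    "graph_similarity",
    "topology_similarity",
    "abs_fractional_difference",
    "icc_a1",
    "build_edge_table",
    "edge_icc",
    "metric_reliability",
    "GlmResult",
    "edge_reliability_glm",
    "presence_attribute_tests",
    "strongest_edges",
    "compare_similarity_distributions",
]


# ---------------------------------------------------------------------------
# Similarity measures
# ---------------------------------------------------------------------------


def _edge_vectors(G1, G2) -> Tuple[np.ndarray, np.ndarray]:
    A1 = G1.adjacency if isinstance(G1, BrainGraph) else np.asarray(G1, dtype=float)
    A2 = G2.adjacency if isinstance(G2, BrainGraph) else np.asarray(G2, dtype=float)
    if A1.shape != A2.shape:
        raise ValueError(f"node-count mismatch: {A1.shape} vs {A2.shape}")
    return upper_triangle(A1), upper_triangle(A2)


def graph_similarity(G1, G2) -> float:
    """Cosine similarity of the unique-edge weight vectors of two graphs.

    Zeros stand in for absent edges, so the measure mixes topology and
    weight agreement; it is 0 if either graph is edgeless.
    """
    v1, v2 = _edge_vectors(G1, G2)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    if np.array_equal(v1, v2):
        return 1.0  # self-comparison is exact, free of rounding noise
    return float(np.dot(v1, v2) / (n1 * n2))


def topology_similarity(G1, G2) -> float:
    """Fraction of unique node pairs on which the two supports agree."""
    v1, v2 = _edge_vectors(G1, G2)
    return float(np.mean((v1 > 0) == (v2 > 0)))


def abs_fractional_difference(w1, w2):
    """|w1 - w2| / ((w1 + w2) / 2), elementwise; in [0, 2].

    Equals 0 for equal weights and exactly 2 when one weight is zero (an
    edge present in only one scan). Undefined when both are zero.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    mean = (w1 + w2) / 2.0
    if np.any(mean == 0):
        raise ValueError("abs_fractional_difference undefined when both weights are 0")
    out = np.abs(w1 - w2) / mean
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc_a1(ratings: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Parameters
    ----------
    ratings:
        Array of shape (n_subjects, k_raters); here the raters are the two
        scan sessions.

    Returns
    -------
    float
        The ICC, possibly negative; NaN when all values are identical (no
        variance to apportion).
    """
    X = np.asarray(ratings, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        return float("nan")
    gm = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((X - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Edge reliability table
# ---------------------------------------------------------------------------


def build_edge_table(
    graphs: Mapping[str, Tuple[BrainGraph, BrainGraph]],
    cmsets: Optional[Mapping[str, Tuple[ConnectivityMatrixSet, ConnectivityMatrixSet]]] = None,
) -> pd.DataFrame:
    """Long-format per-edge reliability table for one scheme.

    Parameters
    ----------
    graphs:
        participant_id -> (scan1 graph, scan2 graph) built under one scheme.
    cmsets:
        Optional participant_id -> (scan1, scan2) connectivity-matrix sets;
        when given, the nine tract attributes of each edge (value in the
        scan where the edge is present, scan 1 when present in both) and
        the absolute between-scan attribute differences are attached.

    Returns
    -------
    DataFrame
        One row per (participant, unique node pair) present in at least one
        scan: weights ``w1``/``w2``, ``presence`` in {both, scan1, scan2},
        ``afd`` (absolute fractional difference; exactly 2 for one-scan
        edges), and optional ``attr_*`` / ``dabs_*`` columns.
    """
    rows: List[dict] = []
    for pid in sorted(graphs):
        g1, g2 = graphs[pid]
        n = g1.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        w1 = g1.adjacency[iu, ju]
        w2 = g2.adjacency[iu, ju]
        present = (w1 > 0) | (w2 > 0)
        idx = np.nonzero(present)[0]
        if cmsets is not None:
            cm1, cm2 = cmsets[pid]
        for e in idx:
            i, j = int(iu[e]), int(ju[e])
            in1, in2 = w1[e] > 0, w2[e] > 0
            presence = "both" if (in1 and in2) else ("scan1" if in1 else "scan2")
            row = {
                "participant_id": pid,
                "i": i,
                "j": j,
                "w1": float(w1[e]),
                "w2": float(w2[e]),
                "presence": presence,
                "afd": abs_fractional_difference(w1[e], w2[e]),
            }
            if cmsets is not None:
                src = cm1 if in1 else cm2
                for metric in METRICS:
                    if metric not in src.matrices:
                        continue
                    a1 = float(src.matrices[metric][i, j])
                    row[f"attr_{metric}"] = a1
                    if in1 and in2 and metric in cm2.matrices:
                        row[f"dabs_{metric}"] = abs(
                            float(cm1.matrices[metric][i, j]) - float(cm2.matrices[metric][i, j])
                        )
                    else:
                        row[f"dabs_{metric}"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def edge_icc(
    edge_table: pd.DataFrame,
    n_participants: int,
    min_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Per-edge ICC of the weights across scans.

    Only edges present in both scans of at least ceil(n_participants *
    min_fraction) participants are eligible (with real 37-participant
    cohorts and the default one-third rule that threshold is 12); edges
    with fewer than three eligible participants get a missing ICC.
    """
    threshold = math.ceil(n_participants * min_fraction)
    records = []
    both = edge_table[edge_table["presence"] == "both"]
    for (i, j), grp in both.groupby(["i", "j"]):
        n_both = len(grp)
        if n_both >= threshold and n_both >= 3:
            icc = icc_a1(grp[["w1", "w2"]].to_numpy())
        else:
            icc = float("nan")
        records.append({"i": i, "j": j, "n_both": n_both, "icc": icc})
    return pd.DataFrame(records)


def metric_reliability(metric_table: pd.DataFrame) -> pd.DataFrame:
    """ICC and mean absolute fractional difference per (metric, item).

    Parameters
    ----------
    metric_table:
        Long-format table with columns ``participant_id``, ``item`` (a node
        label, or ``"global"`` for whole-graph metrics), ``metric``,
        ``scan1``, ``scan2``.

    Returns
    -------
    DataFrame
        One row per (metric, item) with the ICC over participants (missing,
        with a warning, when the metric is constant) and the mean absolute
        fractional difference over participants (pairs where both scans are
        zero are skipped).
    """
    records = []
    constant: Dict[str, int] = {}
    for (metric, item), grp in metric_table.groupby(["metric", "item"]):
        X = grp[["scan1", "scan2"]].to_numpy(dtype=float)
        icc = icc_a1(X)
        if np.isnan(icc) and np.ptp(X) == 0:
            constant[metric] = constant.get(metric, 0) + 1
        nonzero = X.sum(axis=1) != 0
        if nonzero.any():
            afd = abs_fractional_difference(X[nonzero, 0], X[nonzero, 1])
            mean_afd = float(np.mean(np.atleast_1d(afd)))
        else:
            mean_afd = float("nan")
        records.append(
            {"metric": metric, "item": item, "icc": icc, "mean_afd": mean_afd,
             "n": len(grp)}
        )
    for metric, count in constant.items():
        warnings.warn(
            f"metric {metric}: {count} item(s) constant across participants; "
            "ICC undefined (reported missing)"
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# GLM of edge reliability
# ---------------------------------------------------------------------------


@dataclass
class GlmResult:
    """Standardised OLS of edge-weight reliability on tract attributes."""

    coefficients: pd.Series
    pvalues: pd.Series
    significant: pd.Series        # Benjamini-Hochberg FDR flags
    variance_explained: float     # R^2, percent
    n_observations: int
    dropped: Tuple[str, ...]      # aliased / constant predictors removed


def edge_reliability_glm(
    edge_table: pd.DataFrame,
    attributes: Sequence[str] = METRICS,
    fdr_q: float = 0.05,
) -> GlmResult:
    """Regress |fractional difference| of edge weights on tract attributes.

    Uses only edges present in both scans, pooled over participants and
    edges. Predictors are the scan-1 attribute values and the absolute
    between-scan attribute differences (18 for the nine-metric set); the
    dependent and all predictors are z-scored jointly across observations,
    so coefficients are standardised.
    """
    both = edge_table[edge_table["presence"] == "both"]
    if len(both) < 30:
        raise ValueError(f"GLM requires >= 30 both-scan observations, got {len(both)}")
    cols = [f"attr_{m}" for m in attributes] + [f"dabs_{m}" for m in attributes]
    missing = [c for c in cols if c not in both.columns]
    if missing:
        raise ValueError(f"edge table lacks attribute columns: {missing}")
    y = both["afd"].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("dependent variable (afd) has zero variance")
    X = both[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("attribute predictors contain non-finite values")

    dropped: List[str] = []
    keep = []
    for c, col in enumerate(cols):
        if X[:, c].std() == 0:
            dropped.append(col)
        else:
            keep.append(c)
    Xk = X[:, keep]
    names = [cols[c] for c in keep]

    yz = (y - y.mean()) / y.std()
    Xz = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)

    # Drop aliased columns via pivoted QR so the fit is full rank.
    from scipy.linalg import qr

    _, R, piv = qr(Xz, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag[0] * max(Xz.shape) * np.finfo(float).eps)) if diag.size else 0
    if rank < Xz.shape[1]:
        aliased = sorted(piv[rank:])
        for c in aliased:
            dropped.append(names[c])
        keep2 = [c for c in range(Xz.shape[1]) if c not in set(piv[rank:])]
        Xz = Xz[:, keep2]
        names = [names[c] for c in keep2]
        warnings.warn(f"dropped aliased predictors: {dropped}")

    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    coef = pd.Series(model.params[1:], index=names)
    pvals = pd.Series(model.pvalues[1:], index=names)
    reject, _, _, _ = multipletests(pvals.to_numpy(), alpha=fdr_q, method="fdr_bh")
    return GlmResult(
        coefficients=coef,
        pvalues=pvals,
        significant=pd.Series(reject, index=names),
        variance_explained=float(model.rsquared * 100.0),
        n_observations=len(both),
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Presence tests, strongest edges, distribution comparisons
# ---------------------------------------------------------------------------


def presence_attribute_tests(
    edge_table: pd.DataFrame,
    attributes: Sequence[str] = METRICS,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-tests of edge attributes: both-scan vs one-scan edges.

    Compares, per attribute, the distribution over edges present in both
    scans against that over edges present in exactly one scan, with BH-FDR
    correction across the attributes. Groups smaller than two yield missing
    statistics.
    """
    both = edge_table[edge_table["presence"] == "both"]
    single = edge_table[edge_table["presence"] != "both"]
    records = []
    for metric in attributes:
        col = f"attr_{metric}"
        if col not in edge_table.columns:
            continue
        a = both[col].dropna().to_numpy()
        b = single[col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            records.append({"metric": metric, "t": float("nan"), "p": float("nan")})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        records.append({"metric": metric, "t": float(t), "p": float(p)})
    df = pd.DataFrame(records)
    pvals = df["p"].to_numpy()
    ok = np.isfinite(pvals)
    sig = np.zeros(len(df), dtype=bool)
    if ok.any():
        sig[ok], _, _, _ = multipletests(pvals[ok], alpha=fdr_q, method="fdr_bh")
    df["significant"] = sig
    return df


def strongest_edges(
    graphs: Iterable[BrainGraph],
    node_labels: Sequence[str],
    weight_cutoff: float = 0.9,
) -> pd.DataFrame:
    """Rank node pairs by the sum over participants of weights >= cutoff.

    Graphs are expected to be max-1 normalised; weights below the cutoff
    contribute nothing. Returns pairs with positive scores, strongest first
    (ties broken by node-pair order).
    """
    score: Optional[np.ndarray] = None
    for g in graphs:
        A = g.adjacency
        contrib = np.where(A >= weight_cutoff, A, 0.0)
        score = contrib if score is None else score + contrib
    if score is None:
        return pd.DataFrame(columns=["i", "j", "region_i", "region_j", "score"])
    n = score.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = score[iu, ju]
    idx = np.nonzero(vals > 0)[0]
    order = idx[np.lexsort((ju[idx], iu[idx], -vals[idx]))]
    return pd.DataFrame(
        {
            "i": iu[order],
            "j": ju[order],
            "region_i": [node_labels[k] for k in iu[order]],
            "region_j": [node_labels[k] for k in ju[order]],
            "score": vals[order],
        }
    )


def compare_similarity_distributions(
    records: pd.DataFrame,
    group_col: str,
    value_col: str = "graph_similarity",
    participant_col: str = "participant_id",
    fdr_q: float = 0.01,
) -> pd.DataFrame:
    """Paired t-tests between similarity distributions, BH-FDR corrected.

    ``records`` holds one similarity value per (participant, group); all
    group pairs are tested on participants present in both groups
    (participants missing from either member of a pair are dropped with a
    warning). Identical paired samples produce an undefined t and are
    reported as non-significant.
    """
    wide = records.pivot_table(index=participant_col, columns=group_col, values=value_col)
    groups = list(wide.columns)
    rows = []
    for a_idx in range(len(groups)):
        for b_idx in range(a_idx + 1, len(groups)):
            ga, gb = groups[a_idx], groups[b_idx]
            pair = wide[[ga, gb]].dropna()
            if len(pair) < len(wide):
                warnings.warn(
                    f"{len(wide) - len(pair)} participant(s) dropped from pair "
                    f"({ga}, {gb}): missing values"
                )
            if len(pair) < 2 or np.all(pair[ga].to_numpy() == pair[gb].to_numpy()):
                t = p = float("nan")
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    t, p = stats.ttest_rel(pair[ga], pair[gb])
                t, p = float(t), float(p)
            rows.append({"group_a": ga, "group_b": gb, "n": len(pair), "t": t, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    pvals = df["p"].to_numpy()
    ok = np.isfinite(pvals)
    sig = np.zeros(len(df), dtype=bool)
    if ok.any():
        sig[ok], _, _, _ = multipletests(pvals[ok], alpha=fdr_q, method="fdr_bh")
    df["significant"] = sig
    return df
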