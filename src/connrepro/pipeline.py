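"""End-to-end study orchestration.

Ties the stages together: build graphs for a set of construction schemes
(deriving the thresholding sparsity from the nine-metric OMST graphs),
compute the three comparison modes (test-retest, between-scheme, and
between diffusion weightings), the edge- and metric-level reliability
statistics, and the power summary, and shape everything into the report
tables the I/O layer writes.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import Cohort, ConnectivityMatrixSet
from .metrics import compute_global_metrics, compute_node_metrics
from .reproducibility import (
    GlmResult,
    build_edge_table,
    compare_similarity_distributions,
    edge_icc,
    edge_reliability_glm,
    graph_similarity,
    metric_reliability,
    presence_attribute_tests,
    strongest_edges,
    topology_similarity,
)
from .schemes import (
    BrainGraph,
    CORE_SCHEMES,
    SCHEME_REGISTRY,
    SchemeSpec,
    build_graph,
    reference_sparsity_for_thresholding,
)
from .power import summarize_power

__all__ = ["StudyResult", "build_scheme_graphs", "run_study", "inter_b_value_similarity"]

logger = logging.getLogger("connrepro")

GraphsByScheme = Dict[str, Dict[str, Tuple[BrainGraph, BrainGraph]]]


def _content_key(cmset: ConnectivityMatrixSet, spec: SchemeSpec) -> bytes:
    """Content hash over the matrices a scheme reads, for build memoisation.

    Scans with bit-identical inputs (e.g. a zero-noise retest) map to the
    same constructed graph without recomputation.
    """
    h = hashlib.blake2b(digest_size=16)
    h.update(spec.scheme_id.encode())
    for m in sorted(set(spec.topology_metrics) | ({spec.final_weight_metric} & set(cmset.matrices))):
        h.update(m.encode())
        h.update(np.ascontiguousarray(cmset.matrices[m]).tobytes())
    return h.digest()


def build_scheme_graphs(
    cohort: Cohort,
    spec: SchemeSpec,
    reference_sparsity: Optional[float] = None,
    n_draws: int = 2000,
    integration_seed: int = 0,
    cache: Optional[dict] = None,
) -> Dict[str, Tuple[BrainGraph, BrainGraph]]:
    """Build (scan1, scan2) graphs for every participant under one scheme."""
    out: Dict[str, Tuple[BrainGraph, BrainGraph]] = {}
    for pid in cohort.participant_ids:
        pair = []
        for cmset in cohort.scan_pair(pid):
            key = _content_key(cmset, spec) if cache is not None else None
            if key is not None and key in cache:
                template = cache[key]
                graph = BrainGraph(
                    adjacency=template.adjacency,
                    scheme=spec,
                    provenance=(cmset.participant_id, cmset.scan_id, cmset.b_value_label),
                    warnings=template.warnings,
                )
            else:
                graph = build_graph(
                    cmset,
                    spec,
                    reference_sparsity=reference_sparsity,
                    integration_seed=integration_seed,
                    n_draws=n_draws,
                )
                if key is not None:
                    cache[key] = graph
            pair.append(graph)
        out[pid] = (pair[0], pair[1])
    return out


@dataclass
class StudyResult:
    """All outputs of one single-b-value study run."""

    scheme_ids: Tuple[str, ...]
    b_value_label: str
    reference_sparsity: Optional[float]
    graphs: GraphsByScheme
    similarity_records: pd.DataFrame
    between_scheme: Optional[pd.DataFrame]
    scheme_comparison_tests: Optional[pd.DataFrame]
    edge_tables: Dict[str, pd.DataFrame]
    edge_icc_tables: Dict[str, pd.DataFrame]
    glm_results: Dict[str, Optional[GlmResult]]
    presence_tests: Dict[str, pd.DataFrame]
    strongest: Dict[str, pd.DataFrame]
    local_metric_reliability: Optional[pd.DataFrame]
    global_metric_reliability: Optional[pd.DataFrame]
    global_metric_values: Optional[pd.DataFrame]
    power_graph_similarity: Optional[pd.DataFrame]
    warnings: List[str] = field(default_factory=list)

    # -- report-layout tables ------------------------------------------------

    def _similarity_summary(self, value_col: str) -> pd.DataFrame:
        df = self.similarity_records
        g = df.groupby("scheme")[value_col]
        summary = pd.DataFrame({"mean": g.mean(), "SD": g.std(ddof=1)}).T
        summary = summary[[s for s in self.scheme_ids if s in summary.columns]]
        summary.index = pd.MultiIndex.from_product(
            [[self.b_value_label], summary.index], names=["b_value", "stat"]
        )
        return summary

    def tables(self) -> Dict[str, Optional[pd.DataFrame]]:
        tables: Dict[str, Optional[pd.DataFrame]] = {}
        tables["graph_similarity_summary"] = self._similarity_summary("graph_similarity")
        tables["topology_similarity_summary"] = self._similarity_summary("topology_similarity")
        tables["between_scheme_similarity"] = self.between_scheme
        tables["scheme_comparison_tests"] = self.scheme_comparison_tests

        icc_rows = []
        for scheme, table in self.edge_icc_tables.items():
            vals = table["icc"].dropna()
            icc_rows.append(
                {
                    "scheme": scheme,
                    "n_eligible_edges": len(table),
                    "n_icc": len(vals),
                    "mean_icc": vals.mean() if len(vals) else float("nan"),
                    "median_icc": vals.median() if len(vals) else float("nan"),
                    "pct_icc_ge_0.85": 100.0 * (vals >= 0.85).mean() if len(vals) else float("nan"),
                }
            )
        tables["edge_icc_summary"] = pd.DataFrame(icc_rows).set_index("scheme") if icc_rows else None

        glm_rows = []
        for scheme, res in self.glm_results.items():
            if res is None:
                continue
            for name, coef in res.coefficients.items():
                glm_rows.append(
                    {
                        "scheme": scheme,
                        "predictor": name,
                        "coefficient": coef,
                        "p": res.pvalues[name],
                        "significant": bool(res.significant[name]),
                        "variance_explained_pct": res.variance_explained,
                    }
                )
        tables["glm_coefficients"] = pd.DataFrame(glm_rows) if glm_rows else None

        strongest_rows = []
        for scheme, df in self.strongest.items():
            top = df.head(10).copy()
            top.insert(0, "scheme", scheme)
            strongest_rows.append(top)
        tables["strongest_edges"] = (
            pd.concat(strongest_rows, ignore_index=True) if strongest_rows else None
        )

        tables["global_metric_reliability"] = self.global_metric_reliability
        tables["sd_ratios_required_n"] = self.power_graph_similarity

        if self.global_metric_values is not None:
            sds = (
                self.global_metric_values.groupby(["metric", "scan", "scheme"])["value"]
                .std(ddof=1)
                .unstack("scheme")
            )
            tables["global_metric_sds"] = sds
        else:
            tables["global_metric_sds"] = None
        return tables


def _metric_long_table(
    graphs: Mapping[str, Tuple[BrainGraph, BrainGraph]], node_labels: Sequence[str]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Local and global metric values per participant and scan."""
    local_rows = []
    global_rows = []
    local_metrics = ("degree", "clustering", "local_efficiency", "betweenness")
    for pid, (g1, g2) in graphs.items():
        per_scan = {}
        for scan_idx, g in ((1, g1), (2, g2)):
            node_df = compute_node_metrics(g.adjacency, node_labels=node_labels)
            glob = compute_global_metrics(g.adjacency)
            per_scan[scan_idx] = (node_df, glob)
        nd1, gl1 = per_scan[1]
        nd2, gl2 = per_scan[2]
        for metric in local_metrics:
            for node in nd1.index:
                local_rows.append(
                    {
                        "participant_id": pid,
                        "item": node,
                        "metric": metric,
                        "scan1": float(nd1.loc[node, metric]),
                        "scan2": float(nd2.loc[node, metric]),
                    }
                )
        for metric, v1, v2 in (
            ("global_efficiency", gl1.global_efficiency, gl2.global_efficiency),
            ("characteristic_path_length", gl1.characteristic_path_length, gl2.characteristic_path_length),
        ):
            global_rows.append(
                {
                    "participant_id": pid,
                    "item": "global",
                    "metric": metric,
                    "scan1": v1,
                    "scan2": v2,
                }
            )
    return pd.DataFrame(local_rows), pd.DataFrame(global_rows)


def run_study(
    cohort: Cohort,
    scheme_ids: Sequence[str] = CORE_SCHEMES,
    reference_sparsity: Optional[float] = None,
    n_draws: int = 2000,
    integration_seed: int = 0,
    compute_metric_reliability: bool = True,
    run_glm: bool = True,
    strongest_cutoff: float = 0.9,
) -> StudyResult:
    """Run the full reproducibility study on one cohort at one b-value.

    Parameters
    ----------
    cohort:
        Test-retest cohort (two scans per participant).
    scheme_ids:
        Scheme registry keys; defaults to the seven core schemes.
    reference_sparsity:
        Sparsity for the thresholded schemes. When omitted it is derived as
        the cohort-mean sparsity of the nine-metric OMST graphs (which are
        built on demand even if not among ``scheme_ids``).
    n_draws, integration_seed:
        Random-search budget and seed for multi-metric integration.
    compute_metric_reliability, run_glm:
        Optional heavy stages; switched off in quick looks.
    """
    t_start = time.perf_counter()
    warnings_log: List[str] = []
    specs = [SCHEME_REGISTRY[s] for s in scheme_ids]
    cache: dict = {}

    needs_ref = any(
        s.topology_rule == "threshold_top_k" and s.sparsity_target is None for s in specs
    )
    ref = reference_sparsity
    graphs: GraphsByScheme = {}
    if needs_ref and ref is None:
        logger.info("building 9m-OMST graphs to derive the thresholding sparsity")
        ref_spec = SCHEME_REGISTRY["9m-OMST"]
        ref_graphs = build_scheme_graphs(
            cohort, ref_spec, n_draws=n_draws, integration_seed=integration_seed, cache=cache
        )
        ref = reference_sparsity_for_thresholding(
            [g for pair in ref_graphs.values() for g in pair]
        )
        logger.info("reference sparsity (mean 9m-OMST): %.4f", ref)
        if "9m-OMST" in scheme_ids:
            graphs["9m-OMST"] = ref_graphs

    for spec in specs:
        if spec.scheme_id in graphs:
            continue
        t0 = time.perf_counter()
        graphs[spec.scheme_id] = build_scheme_graphs(
            cohort,
            spec,
            reference_sparsity=ref,
            n_draws=n_draws,
            integration_seed=integration_seed,
            cache=cache,
        )
        logger.info("built %-12s graphs in %.1fs", spec.scheme_id, time.perf_counter() - t0)

    # Mode 1: test-retest similarity.
    sim_rows = []
    for scheme in scheme_ids:
        for pid, (g1, g2) in graphs[scheme].items():
            sim_rows.append(
                {
                    "scheme": scheme,
                    "participant_id": pid,
                    "b_value": cohort.b_value_label,
                    "comparison_kind": "test_retest",
                    "graph_similarity": graph_similarity(g1, g2),
                    "topology_similarity": topology_similarity(g1, g2),
                }
            )
    similarity_records = pd.DataFrame(sim_rows)

    # Mode 2: between-scheme agreement (mean over participants and scans).
    between = None
    scheme_tests = None
    if len(scheme_ids) >= 2:
        mat = pd.DataFrame(np.nan, index=list(scheme_ids), columns=list(scheme_ids))
        for a_idx in range(len(scheme_ids)):
            for b_idx in range(a_idx + 1, len(scheme_ids)):
                sa, sb = scheme_ids[a_idx], scheme_ids[b_idx]
                vals = []
                for pid in cohort.participant_ids:
                    for scan in (0, 1):
                        vals.append(
                            graph_similarity(graphs[sa][pid][scan], graphs[sb][pid][scan])
                        )
                mat.loc[sb, sa] = float(np.mean(vals))
        between = mat
        scheme_tests = compare_similarity_distributions(
            similarity_records, group_col="scheme", fdr_q=0.01
        )

    # Edge-level reliability per scheme.
    edge_tables = {}
    icc_tables = {}
    glm_results: Dict[str, Optional[GlmResult]] = {}
    presence = {}
    strongest_by_scheme = {}
    cm_pairs = {pid: cohort.scan_pair(pid) for pid in cohort.participant_ids}
    for scheme in scheme_ids:
        t0 = time.perf_counter()
        table = build_edge_table(graphs[scheme], cm_pairs)
        edge_tables[scheme] = table
        icc_tables[scheme] = edge_icc(table, cohort.n_participants)
        if run_glm:
            try:
                glm_results[scheme] = edge_reliability_glm(table)
            except ValueError as exc:
                glm_results[scheme] = None
                warnings_log.append(f"GLM skipped for {scheme}: {exc}")
        else:
            glm_results[scheme] = None
        presence[scheme] = presence_attribute_tests(table)
        strongest_by_scheme[scheme] = strongest_edges(
            [graphs[scheme][pid][0] for pid in cohort.participant_ids],
            cohort.node_labels,
            weight_cutoff=strongest_cutoff,
        )
        logger.info("edge statistics for %-12s in %.1fs", scheme, time.perf_counter() - t0)

    # Metric-level reliability per scheme.
    local_rel = global_rel = global_vals = None
    if compute_metric_reliability:
        local_frames = []
        global_frames = []
        value_frames = []
        for scheme in scheme_ids:
            t0 = time.perf_counter()
            local_tbl, global_tbl = _metric_long_table(graphs[scheme], cohort.node_labels)
            rel_local = metric_reliability(local_tbl)
            rel_local.insert(0, "scheme", scheme)
            local_frames.append(rel_local)
            rel_global = metric_reliability(global_tbl)
            rel_global.insert(0, "scheme", scheme)
            global_frames.append(rel_global)
            for scan_col, scan_name in (("scan1", "S1"), ("scan2", "S2")):
                vf = global_tbl[["participant_id", "metric", scan_col]].rename(
                    columns={scan_col: "value"}
                )
                vf["scan"] = scan_name
                vf["scheme"] = scheme
                value_frames.append(vf)
            logger.info(
                "graph-theory metrics for %-12s in %.1fs", scheme, time.perf_counter() - t0
            )
        local_rel = pd.concat(local_frames, ignore_index=True)
        global_rel_long = pd.concat(global_frames, ignore_index=True)
        global_rel = global_rel_long.pivot_table(
            index="metric", columns="scheme", values=["icc", "mean_afd"]
        )
        global_vals = pd.concat(value_frames, ignore_index=True)

    # Power summary from the graph-similarity distributions.
    power_tbl = None
    dists = {
        scheme: grp["graph_similarity"].to_numpy()
        for scheme, grp in similarity_records.groupby("scheme")
    }
    reference = "NS-thr" if "NS-thr" in dists else None
    if len(dists) >= 2:
        try:
            power_tbl = summarize_power(dists, reference_scheme=reference)
        except ValueError as exc:
            warnings_log.append(f"power summary skipped: {exc}")

    logger.info("study complete in %.1fs", time.perf_counter() - t_start)
    return StudyResult(
        scheme_ids=tuple(scheme_ids),
        b_value_label=cohort.b_value_label,
        reference_sparsity=ref,
        graphs=graphs,
        similarity_records=similarity_records,
        between_scheme=between,
        scheme_comparison_tests=scheme_tests,
        edge_tables=edge_tables,
        edge_icc_tables=icc_tables,
        glm_results=glm_results,
        presence_tests=presence,
        strongest=strongest_by_scheme,
        local_metric_reliability=local_rel,
        global_metric_reliability=global_rel,
        global_metric_values=global_vals,
        power_graph_similarity=power_tbl,
        warnings=warnings_log,
    )


def inter_b_value_similarity(results: Mapping[str, StudyResult]) -> pd.DataFrame:
    """Mode 3: similarity of graphs built from different diffusion weightings.

    ``results`` maps b-value labels to study results over the *same*
    participants. For every scheme, participant, scan and pair of b-values,
    the graph and topology similarity of the two graphs is recorded.
    """
    labels = sorted(results)
    rows = []
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            la, lb = labels[a_idx], labels[b_idx]
            ra, rb = results[la], results[lb]
            shared_schemes = [s for s in ra.scheme_ids if s in rb.scheme_ids]
            for scheme in shared_schemes:
                shared_pids = sorted(set(ra.graphs[scheme]) & set(rb.graphs[scheme]))
                for pid in shared_pids:
                    for scan in (0, 1):
                        ga = ra.graphs[scheme][pid][scan]
                        gb = rb.graphs[scheme][pid][scan]
                        rows.append(
                            {
                                "scheme": scheme,
                                "participant_id": pid,
                                "scan": f"scan{scan + 1}",
                                "b_a": la,
                                "b_b": lb,
                                "comparison_kind": "inter_b_value",
                                "graph_similarity": graph_similarity(ga, gb),
                                "topology_similarity": topology_similarity(ga, gb),
                            }
                        )
    return pd.DataFrame(rows)
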