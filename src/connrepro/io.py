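"""Cohort and report I/O.

Connectivity matrices travel as plain delimited text: one N x N matrix per
file, tab-separated, no header, full float precision. A cohort manifest is
a CSV with one row per (participant, scan, b-value) and one path column per
metric, plus a ``node_labels.txt`` (one region name per line) alongside it.
Result tables are written as CSV files mirroring the report layouts of the
study (similarity summaries, between-scheme matrix, ICC summaries, GLM
coefficients, strongest edges, SD ratios / required-N).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .containers import Cohort, ConnectivityMatrixSet, METRICS
from .synthetic import SyntheticConfig

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "load_cohort",
    "load_synthetic_config",
    "write_report_tables",
]

logger = logging.getLogger("connrepro")

_MANIFEST_KEYS = ("participant_id", "scan_id", "b_value_label")


def write_matrix(W: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.asarray(W, dtype=float), delimiter="\t", fmt="%.17g")


def read_matrix(path: Path) -> np.ndarray:
    try:
        W = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell or malformed matrix ({exc})") from exc
    return W


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as matrix files plus manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    rows = []
    for cmset in cohort.iter_sets():
        row = {
            "participant_id": cmset.participant_id,
            "scan_id": cmset.scan_id,
            "b_value_label": cmset.b_value_label,
        }
        for metric in METRICS:
            if metric not in cmset.matrices:
                continue
            rel = f"matrices/{cmset.participant_id}_{cmset.scan_id}_{metric}.tsv"
            write_matrix(cmset.matrices[metric], out / rel)
            row[metric] = rel
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "node_labels.txt").write_text("\n".join(cohort.node_labels) + "\n")
    return out / "manifest.csv"


def _symmetrize(W: np.ndarray, where: str) -> np.ndarray:
    scale = max(float(np.abs(W).max(initial=0.0)), 1e-300)
    asym = float(np.abs(W - W.T).max(initial=0.0)) / scale
    if asym > 1e-8:
        raise ValueError(f"{where}: matrix asymmetric (relative asymmetry {asym:.3g})")
    return (W + W.T) / 2.0


def load_cohort(manifest_path, metrics: Sequence[str] = METRICS) -> Cohort:
    """Load and validate a cohort from a manifest.

    Matrices are symmetrised by averaging when the relative asymmetry is at
    most 1e-8 (hard error otherwise) and their diagonals are zeroed
    unconditionally, since diagonal entries would represent self-connections.
    Every participant must have exactly the two scans per b-value label.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for key in _MANIFEST_KEYS:
        if key not in manifest.columns:
            raise ValueError(f"manifest lacks required column {key!r}")
    missing_metric_cols = [m for m in metrics if m not in manifest.columns]
    if missing_metric_cols:
        raise ValueError(f"manifest lacks metric path columns: {missing_metric_cols}")

    labels_path = manifest_path.parent / "node_labels.txt"
    if not labels_path.exists():
        raise ValueError(f"node label file not found: {labels_path}")
    node_labels = tuple(labels_path.read_text().split())

    b_values = manifest["b_value_label"].unique()
    if len(b_values) != 1:
        raise ValueError(
            f"manifest mixes b-value labels {sorted(map(str, b_values))}; load one at a time"
        )

    scans_per_pid = manifest.groupby("participant_id")["scan_id"].apply(sorted)
    for pid, scans in scans_per_pid.items():
        if scans != ["scan1", "scan2"]:
            raise ValueError(
                f"participant {pid}: expected exactly scans ['scan1', 'scan2'], got {scans}"
            )

    n = len(node_labels)
    participants: Dict[str, Dict[str, ConnectivityMatrixSet]] = {}
    for _, row in manifest.iterrows():
        pid, scan_id = row["participant_id"], row["scan_id"]
        matrices = {}
        for metric in metrics:
            rel = row[metric]
            path = manifest_path.parent / rel
            if not path.exists():
                raise ValueError(f"participant {pid}/{scan_id}: file not found: {path}")
            W = read_matrix(path)
            if W.shape != (n, n):
                raise ValueError(
                    f"participant {pid}/{scan_id}/{metric}: shape {W.shape} "
                    f"does not match the {n} node labels"
                )
            W = _symmetrize(W, f"participant {pid}/{scan_id}/{metric}")
            np.fill_diagonal(W, 0.0)
            if W.min() < 0:
                raise ValueError(f"participant {pid}/{scan_id}/{metric}: negative entries")
            matrices[metric] = W
        participants.setdefault(pid, {})[scan_id] = ConnectivityMatrixSet(
            participant_id=str(pid),
            scan_id=str(scan_id),
            b_value_label=str(row["b_value_label"]),
            matrices=matrices,
            node_labels=node_labels,
        )
    return Cohort(
        node_labels=node_labels,
        b_value_label=str(b_values[0]),
        participants=participants,
        provenance={"manifest": str(manifest_path)},
    )


def load_synthetic_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SyntheticConfig(**data)


#: Report-table names written by write_report_tables, in the order emitted.
REPORT_TABLES = (
    "graph_similarity_summary",
    "topology_similarity_summary",
    "between_scheme_similarity",
    "scheme_comparison_tests",
    "edge_icc_summary",
    "glm_coefficients",
    "strongest_edges",
    "global_metric_reliability",
    "sd_ratios_required_n",
    "global_metric_sds",
)


def write_report_tables(tables: Mapping[str, Optional[pd.DataFrame]], out_dir) -> Dict[str, Path]:
    """Write available result tables as CSV files; log (don't fail on) gaps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name in REPORT_TABLES:
        df = tables.get(name)
        if df is None or (hasattr(df, "empty") and df.empty):
            logger.warning("report table %s missing or empty; skipped", name)
            continue
        path = out / f"{name}.csv"
        df.to_csv(path)
        written[name] = path
    for name, df in tables.items():
        if name not in REPORT_TABLES and df is not None and not df.empty:
            path = out / f"{name}.csv"
            df.to_csv(path)
            written[name] = path
    return written
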