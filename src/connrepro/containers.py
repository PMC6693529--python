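"""Core in-memory containers for multi-metric structural connectivity data.

A *connectivity matrix* (CM) is a symmetric node-by-node matrix whose (i, j)
entry summarises one attribute of the reconstructed white-matter connection
between cerebrum regions i and j. Nine tract metrics are carried per scan:

====  =========================================
FA    fractional anisotropy (dimensionless, in (0, 1))
MD    mean diffusivity (1e-3 mm^2/s)
RD    radial diffusivity (1e-3 mm^2/s)
NS    number of streamlines
PS    percentage of streamlines (sums to 1 over unique connections)
SLD   streamline density
TV    tract volume
TL    tract length (mm)
ED    Euclidean distance between node centroids (mm)
====  =========================================

All nine matrices of one scan describe the same set of reconstructed tracts,
so they share a common support: a node pair either carries all nine metrics
(positive values) or none (zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

#: Canonical metric order used throughout the package.
METRICS: Tuple[str, ...] = ("FA", "MD", "RD", "NS", "PS", "SLD", "TV", "TL", "ED")

SCAN_IDS: Tuple[str, str] = ("scan1", "scan2")

#: The 90 cerebrum regions of the AAL atlas, in standard atlas order.
#: Used as default node labels for 90-node cohorts.
AAL90_LABELS: Tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)


def default_node_labels(n_nodes: int) -> Tuple[str, ...]:
    """AAL-90 labels when ``n_nodes == 90``, generic region names otherwise."""
    if n_nodes == 90:
        return AAL90_LABELS
    return tuple(f"Region_{k + 1:03d}" for k in range(n_nodes))


def validate_adjacency(
    W: np.ndarray,
    name: str = "matrix",
    sym_tol: float = 1e-12,
    require_nonnegative: bool = True,
) -> None:
    """Check that ``W`` is a valid symmetric zero-diagonal adjacency matrix.

    Raises
    ------
    ValueError
        If the matrix is not square, not finite, asymmetric beyond ``sym_tol``
        (absolute, relative to the largest magnitude), has a non-zero diagonal,
        or (optionally) has negative entries.
    """
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name}: expected a square matrix, got shape {W.shape}")
    if not np.issubdtype(W.dtype, np.number):
        raise ValueError(f"{name}: non-numeric dtype {W.dtype}")
    if not np.all(np.isfinite(W)):
        raise ValueError(f"{name}: contains non-finite entries")
    scale = max(float(np.abs(W).max(initial=0.0)), 1.0)
    if np.abs(W - W.T).max(initial=0.0) > sym_tol * scale:
        raise ValueError(f"{name}: not symmetric within tolerance {sym_tol}")
    if np.abs(np.diag(W)).max(initial=0.0) > 0:
        raise ValueError(f"{name}: diagonal must be zero")
    if require_nonnegative and W.min(initial=0.0) < 0:
        raise ValueError(f"{name}: negative entries are not allowed")


def upper_triangle(W: np.ndarray) -> np.ndarray:
    """Vector of the N(N-1)/2 unique-pair entries of ``W`` (row-major, i<j)."""
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.asarray(W)[iu]


def matrix_sparsity(W: np.ndarray) -> float:
    """Fraction of unique node pairs carrying a positive weight."""
    v = upper_triangle(W)
    return float(np.count_nonzero(v > 0)) / v.size


@dataclass
class ConnectivityMatrixSet:
    """One scan's nine metric-keyed connectivity matrices for one participant.

    Invariants (enforced by :meth:`validate`, called on construction):

    * every matrix is symmetric (tol 1e-12), zero-diagonal and non-negative;
    * the matrices share a common support — a node pair has either all
      metrics positive or all zero;
    * PS sums to 1 over unique connections whenever any connection exists.
    """

    participant_id: str
    scan_id: str
    b_value_label: str
    matrices: Dict[str, np.ndarray]
    node_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        self.validate()

    # -- properties ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def support(self) -> np.ndarray:
        """Boolean matrix of pairs carrying a reconstructed connection."""
        first = next(iter(self.matrices.values()))
        return first > 0

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.scan_id not in SCAN_IDS:
            raise ValueError(f"scan_id must be one of {SCAN_IDS}, got {self.scan_id!r}")
        unknown = set(self.matrices) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metric keys: {sorted(unknown)}")
        if not self.matrices:
            raise ValueError("matrices mapping is empty")
        n = self.n_nodes
        ref_support = None
        for metric in METRICS:
            if metric not in self.matrices:
                continue
            W = np.asarray(self.matrices[metric], dtype=float)
            if W.shape != (n, n):
                raise ValueError(
                    f"{self.participant_id}/{self.scan_id}/{metric}: "
                    f"shape {W.shape} does not match {n} node labels"
                )
            validate_adjacency(W, name=f"{self.participant_id}/{self.scan_id}/{metric}")
            self.matrices[metric] = W
            supp = W > 0
            if ref_support is None:
                ref_support = supp
            elif not np.array_equal(supp, ref_support):
                raise ValueError(
                    f"{self.participant_id}/{self.scan_id}: metric {metric} does not "
                    "share the common support of the other metrics"
                )
        if "PS" in self.matrices and ref_support is not None and ref_support.any():
            total = float(upper_triangle(self.matrices["PS"]).sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.participant_id}/{self.scan_id}: PS sums to {total}, expected 1"
                )


@dataclass
class Cohort:
    """A test-retest cohort: participant -> scan -> ConnectivityMatrixSet."""

    node_labels: Tuple[str, ...]
    b_value_label: str
    participants: Dict[str, Dict[str, ConnectivityMatrixSet]]
    provenance: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> List[str]:
        return sorted(self.participants)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def scan_pair(self, participant_id: str) -> Tuple[ConnectivityMatrixSet, ConnectivityMatrixSet]:
        scans = self.participants[participant_id]
        return scans["scan1"], scans["scan2"]

    @property
    def records(self) -> List[Tuple[str, ConnectivityMatrixSet, ConnectivityMatrixSet]]:
        """Participant records as (participant_id, scan1 set, scan2 set)."""
        return [(pid, *self.scan_pair(pid)) for pid in self.participant_ids]

    def iter_sets(self) -> Iterator[ConnectivityMatrixSet]:
        for pid in self.participant_ids:
            for scan_id in SCAN_IDS:
                yield self.participants[pid][scan_id]
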