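"""Graph-construction schemes for structural brain networks.

A *scheme* specifies (1) the initial edge weights (one tract metric, or a
data-driven linear combination of several), (2) the topology rule (OMST
filtering, or keeping the top-K edges by initial weight at a prescribed
sparsity), and (3) the final edge weights (the initial weights, or a
re-weighting of the selected node pairs by a different metric).

Twenty schemes are registered. The first seven carry the abbreviations used
throughout the reporting layer (NS-OMST, NS+FA-OMST, 9m-OMST, NS-thr,
NS-t/FA-w, NS-t/MD-w, FA-t/NS-w); the remainder are numbered ``scheme-08``
.. ``scheme-20``.

Construction conventions:

* Initial weights are rescaled to maximum 1 before topology selection, so
  the OMST efficiency/cost trade-off is evaluated on a common scale for
  every scheme; the final graph is normalised to maximum weight 1 as well.
* Top-K selection rounds K = sparsity * N(N-1)/2 half-up and breaks weight
  ties by lexicographic node-pair order, so results are deterministic.
* Thresholded graphs are not forced to be connected; connectivity is only
  guaranteed inside OMST.
* Thresholded schemes take their sparsity from the cohort-mean sparsity of
  the nine-metric OMST graphs (see
  :func:`reference_sparsity_for_thresholding`) unless an explicit target is
  given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .containers import ConnectivityMatrixSet, METRICS, matrix_sparsity
from .omst import integrate_metrics, omst_filter

__all__ = [
    "SchemeSpec",
    "BrainGraph",
    "SCHEME_REGISTRY",
    "CORE_SCHEMES",
    "build_graph",
    "reference_sparsity_for_thresholding",
]

TOPOLOGY_RULES = ("omst", "threshold_top_k")


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one graph-construction scheme."""

    scheme_id: str
    topology_rule: str
    topology_metrics: Tuple[str, ...]
    final_weight_metric: str = "same-as-topology"
    sparsity_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.topology_rule not in TOPOLOGY_RULES:
            raise ValueError(f"unknown topology rule {self.topology_rule!r}")
        unknown = set(self.topology_metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown topology metrics: {sorted(unknown)}")
        if self.final_weight_metric not in METRICS + ("same-as-topology", "integrated"):
            raise ValueError(f"unknown final weight metric {self.final_weight_metric!r}")
        if self.sparsity_target is not None and not 0 < self.sparsity_target <= 1:
            raise ValueError("sparsity_target must lie in (0, 1]")


@dataclass
class BrainGraph:
    """A constructed brain network with scheme and scan provenance.

    The adjacency is symmetric and non-negative with zero diagonal; if any
    edge exists its maximum weight is exactly 1.
    """

    adjacency: np.ndarray
    scheme: SchemeSpec
    provenance: Tuple[str, str, str]    # (participant_id, scan_id, b_value_label)
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def sparsity(self) -> float:
        return matrix_sparsity(self.adjacency)


NINE = ("FA", "MD", "RD", "NS", "PS", "SLD", "TV", "TL", "ED")

# The registry expresses all 20 rows of the construction-scheme table.
# Rows 12 and 13 of the source table list a metric "PT" that does not appear
# in the nine-metric list; it is taken to mean PS (percentage of streamlines)
# and recorded as such here rather than silently resolved elsewhere.
SCHEME_REGISTRY: Dict[str, SchemeSpec] = {
    s.scheme_id: s
    for s in (
        SchemeSpec("NS-OMST", "omst", ("NS",)),
        SchemeSpec("NS+FA-OMST", "omst", ("NS", "FA"), "integrated"),
        SchemeSpec("9m-OMST", "omst", NINE, "integrated"),
        SchemeSpec("NS-thr", "threshold_top_k", ("NS",)),
        SchemeSpec("NS-t/FA-w", "threshold_top_k", ("NS",), "FA"),
        SchemeSpec("NS-t/MD-w", "threshold_top_k", ("NS",), "MD"),
        SchemeSpec("FA-t/NS-w", "threshold_top_k", ("FA",), "NS"),
        SchemeSpec("scheme-08", "omst", ("NS", "FA", "MD"), "integrated"),
        SchemeSpec("scheme-09", "omst", ("NS", "FA", "MD", "SLD"), "integrated"),
        SchemeSpec("scheme-10", "omst", ("NS", "FA", "MD", "SLD", "TL"), "integrated"),
        SchemeSpec("scheme-11", "omst", ("NS", "FA", "MD", "SLD", "TL", "TV"), "integrated"),
        # "PT" in the source table -> PS here.
        SchemeSpec("scheme-12", "omst", ("NS", "FA", "MD", "SLD", "TL", "TV", "PS"), "integrated"),
        SchemeSpec("scheme-13", "omst", ("NS", "FA", "MD", "SLD", "TL", "TV", "PS", "ED"), "integrated"),
        SchemeSpec("scheme-14", "threshold_top_k", ("FA",)),
        # Highest-MD edges kept as stated, without inversion, despite MD's
        # inverse physiological reading.
        SchemeSpec("scheme-15", "threshold_top_k", ("MD",)),
        SchemeSpec("scheme-16", "omst", ("FA",)),
        SchemeSpec("scheme-17", "omst", ("MD",)),
        SchemeSpec("scheme-18", "threshold_top_k", ("FA",), "MD"),
        SchemeSpec("scheme-19", "threshold_top_k", ("MD",), "NS"),
        SchemeSpec("scheme-20", "threshold_top_k", ("MD",), "FA"),
    )
}

#: The seven schemes analysed in detail by the reporting layer.
CORE_SCHEMES: Tuple[str, ...] = (
    "NS-OMST", "NS+FA-OMST", "9m-OMST", "NS-thr", "NS-t/FA-w", "NS-t/MD-w", "FA-t/NS-w",
)


def _top_k_mask(W: np.ndarray, sparsity: float) -> Tuple[np.ndarray, Optional[str]]:
    """Boolean mask keeping the K strongest unique edges, half-up rounding."""
    n = W.shape[0]
    m = n * (n - 1) // 2
    k = int(np.floor(sparsity * m + 0.5))
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    pos = np.nonzero(w > 0)[0]
    note = None
    if k > pos.size:
        note = (
            f"requested {k} edges at sparsity {sparsity:.4f} but only "
            f"{pos.size} positive edges exist; keeping all"
        )
        warnings.warn(note)
        k = pos.size
    # Sort by (-weight, i, j): ties broken lexicographically.
    order = pos[np.lexsort((ju[pos], iu[pos], -w[pos]))]
    keep = order[:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    return mask | mask.T, note


def build_graph(
    cmset: ConnectivityMatrixSet,
    spec: SchemeSpec,
    reference_sparsity: Optional[float] = None,
    integration_seed: int = 0,
    n_draws: int = 2000,
    max_rounds: Optional[int] = None,
) -> BrainGraph:
    """Construct a brain network from one scan's connectivity matrices.

    Parameters
    ----------
    cmset:
        The scan's metric-keyed connectivity matrices.
    spec:
        The construction scheme.
    reference_sparsity:
        Target sparsity for ``threshold_top_k`` schemes whose spec carries
        no explicit ``sparsity_target`` (normally the cohort-mean sparsity
        of the nine-metric OMST graphs).
    integration_seed, n_draws:
        Passed to :func:`connrepro.omst.integrate_metrics` for multi-metric
        schemes. The seed does not vary with the scan, so identical input
        matrices yield identical integrated graphs.
    max_rounds:
        Optional cap on OMST rounds.
    """
    missing = [m for m in spec.topology_metrics if m not in cmset.matrices]
    if spec.final_weight_metric in METRICS and spec.final_weight_metric not in cmset.matrices:
        missing.append(spec.final_weight_metric)
    if missing:
        raise ValueError(
            f"{cmset.participant_id}/{cmset.scan_id}: metrics {missing} required by "
            f"scheme {spec.scheme_id} are not present"
        )
    notes = []

    # 1. Initial weights (rescaled to max 1 before topology selection).
    if len(spec.topology_metrics) == 1:
        W0 = np.array(cmset.matrices[spec.topology_metrics[0]], dtype=float)
    else:
        result = integrate_metrics(
            [cmset.matrices[m] for m in spec.topology_metrics],
            seed=integration_seed,
            n_draws=n_draws,
        )
        W0 = result.integrated_matrix
    mx = W0.max(initial=0.0)
    if mx > 0:
        W0 = W0 / mx

    # 2. Topology.
    if spec.topology_rule == "omst":
        mask = omst_filter(W0, max_rounds=max_rounds).selected_mask
    else:
        sparsity = spec.sparsity_target if spec.sparsity_target is not None else reference_sparsity
        if sparsity is None:
            raise ValueError(
                f"scheme {spec.scheme_id} needs a sparsity_target or reference_sparsity"
            )
        mask, note = _top_k_mask(W0, sparsity)
        if note:
            notes.append(note)

    # 3. Final weights.
    if spec.final_weight_metric in ("same-as-topology", "integrated"):
        Wf = np.where(mask, W0, 0.0)
    else:
        Wf = np.where(mask, cmset.matrices[spec.final_weight_metric], 0.0)
        dropped = int(np.count_nonzero(mask) - np.count_nonzero(Wf)) // 2
        if dropped:
            note = (
                f"{dropped} retained pair(s) have zero {spec.final_weight_metric} "
                "and were dropped on re-weighting"
            )
            warnings.warn(note)
            notes.append(note)

    # 4. Normalise to maximum edge weight 1.
    mx = Wf.max(initial=0.0)
    if mx > 0:
        Wf = Wf / mx

    return BrainGraph(
        adjacency=Wf,
        scheme=spec,
        provenance=(cmset.participant_id, cmset.scan_id, cmset.b_value_label),
        warnings=tuple(notes),
    )


def reference_sparsity_for_thresholding(omst_graphs: Iterable[BrainGraph]) -> float:
    """Cohort-mean sparsity of the nine-metric OMST graphs.

    The four thresholded schemes are all matched to this single value so
    their per-participant edge counts coincide.
    """
    sparsities = [g.sparsity for g in omst_graphs]
    if not sparsities:
        raise ValueError("no OMST graphs supplied: cannot derive a reference sparsity")
    return float(np.mean(sparsities))
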