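# Methods

This note documents the models, conventions and numerical choices behind
`connrepro`, in the order data flows through the package.

## Synthetic test-retest cohorts

The generator (`connrepro.synthetic`) emulates a cohort of participants
scanned twice, each scan yielding nine symmetric connectivity matrices
(FA, MD, RD, NS, PS, SLD, TV, TL, ED) over a fixed node set. It is built
around three ideas.

**A cohort-level anatomical backbone.** Node coordinates are drawn once per
cohort (uniform in a 100-unit box, standing in for atlas region centroids),
and a wiring-propensity field over node pairs decays with inter-node
distance (decay length 0.4 × box size) plus shared Gumbel noise. Each
participant's connectome support is the top `density · N(N−1)/2` pairs of
this field after a participant-specific Gumbel jitter (scale 0.5), unioned
with a random spanning tree that guarantees connectedness. Sharing the
backbone is essential: real cohorts built on a common atlas have strong
cross-participant overlap in their edge sets, and the edge-ICC eligibility
rule (an edge must appear in both scans of at least one third of the
cohort) is vacuous without it. Group-level edge fields (the latent NS, the
logit-FA field, the MD field, the RD/MD ratio, the TV and TL deviations)
are likewise drawn once per cohort, with participant-level deviations on
top, so that edges have stable identities across participants while
between-participant variance remains for the ICC to apportion.

**Realistic marginals and couplings.** NS has a discretised Pareto tail
(default exponent 2.0; scan-1 counts are `ceil(3·(1+Pareto))` times a
log-normal participant deviation of SD 0.4), so a few connections dominate
— in max-1-normalised NS-weighted graphs only a few edges approach 1. MD is
log-normal with a small coefficient of variation (default 0.05, split
evenly between group and participant levels), reflecting how uniform MD is
across white-matter tracts; RD is MD times a pair-level factor in
(0.5, 1.5). TV grows with NS (`0.5·NS^0.8` times log-normal noise), SLD is
the ratio NS/TV in the latent (scan-1) connectome, TL exceeds the Euclidean
node distance ED by a positive pair-level factor, and PS is NS renormalised
to sum to 1 per scan. FA is a logit-normal in (0, 1).

**Calibrated retest noise.** Scan 2 perturbs scan 1 in a
variance-stabilised domain — log for NS/TV/SLD, logit for FA, identity for
MD/RD/TL/ED (identity-domain values are floored at 1e-6 to keep the support
invariant) — with one global noise scale per metric found by bisection so
the pooled scan-scan Pearson correlation over the cohort hits the
configured target (default 0.9 for every metric, comfortably inside the
≥ 0.83 regime reported for tract attributes in real scan-rescan data; 60
bisection iterations, which is well past float resolution). Three design
points deserve note:

* **ED is perturbed too.** Geometrically ED would be identical across
  scans, but region centroids are re-derived per scan in practice, and a
  per-metric correlation target cannot be met by a constant; ED gets
  identity-domain noise plus a participant-level head-size jitter.
* **SLD is calibrated directly** rather than recomputed as NS₂/TV₂. The
  tight NS–TV coupling makes the correlation of their ratio fall far below
  any per-metric target; SLD = NS/TV holds exactly in the latent scan-1
  connectome, and scan-2 SLD gets its own log-domain noise.
* **PS is derived, not calibrated** — renormalising NS per scan preserves
  the sum-to-1 invariant, and its retest correlation tracks NS's closely
  because the per-scan normaliser is nearly common.

A `retest_correlation` of exactly 1 copies scan 1 bit-for-bit (no
transform round-trip), so the zero-noise limit is exact. Dropout then
zeroes all nine metrics of a Bernoulli(`dropout_rate`, default 0.2)
selection of the lowest-NS-quartile connections in exactly one randomly
chosen scan per connection, emulating the preferential loss of weak,
low-volume tracts between scans. Identical (config, seed) pairs are
bit-identical; unreachable correlation targets are recorded as provenance
warnings, not errors.

What the generator does **not** emulate: diffusion physics, tractography
biases (gyral bias, crossing-fibre failures), distance-dependent error
correlations between metrics, any b-value dependence, or hemispheric
symmetry. Passing tests therefore certify the statistical machinery —
estimator calibration, contracts, pipeline plumbing — not claims about any
particular scanner or tractography algorithm.

## Graph construction

All twenty registered schemes follow the same four steps (see
`connrepro.schemes`):

1. **Initial weights** — one metric matrix, or for multi-metric schemes the
   diffusion-distance-optimal simplex mixture (below). Initial weights are
   rescaled to maximum 1 *before* topology selection, so the OMST
   efficiency/cost trade-off is evaluated on a common scale across schemes
   (the ordering of normalisation and filtering is a convention this
   package fixes; both appear in the literature).
2. **Topology** — OMST filtering, or top-K thresholding with
   K = round-half-up(sparsity · N(N−1)/2) and weight ties broken by
   lexicographic node-pair order for determinism. Thresholded schemes
   default to the cohort-mean sparsity of the nine-metric OMST graphs, so
   all four thresholded schemes share per-participant edge counts.
   Thresholded graphs are *not* forced to be connected; only OMST
   guarantees connectivity.
3. **Final weights** — the initial weights on the selected pairs, or a
   re-weighting by a different metric on the same pairs (a zero re-weight
   value drops the edge with a warning). MD-based selection keeps the
   *highest*-MD edges as specified, without inversion, despite MD's inverse
   physiological reading.
4. **Normalisation** — the final graph is scaled to maximum edge weight
   exactly 1.

Topologies are per participant and per scan; no group mask is imposed.

### OMST

Minimal spanning trees use Kruskal on edge length 1/weight with ties broken
by (length, i, j), making every round deterministic. Rounds continue until
the residual graph no longer connects the non-isolated nodes (or
`max_rounds`). Cost is normalised by the total input edge weight so it lies
in [0, 1] and is commensurate with the global efficiency of a max-1 graph.
A spanning-tree input returns itself after one round; a disconnected input
is an error.

### Diffusion-distance integration

The graph diffusion distance is maximised over a fixed log-spaced time grid
(20 points in [1e-2, 10]) rather than optimised continuously — reproducible,
fast, and a config knob. Heat-kernel Frobenius distances are evaluated
spectrally via the trace identity
‖K_A − K_B‖² = Σe^{−2ta} + Σe^{−2tb} − 2Σ_{pq} e^{−ta_p}e^{−tb_q}(u_p·v_q)²,
which avoids forming kernels and makes the mixture search cheap.

The mixing coefficients minimise the summed distance from the mixture to
each (max-1-rescaled) input. This objective is one concrete instantiation
of "combine the metrics so the mixture stays close to all of them"; the
original formulation of the integration step is described only loosely in
the literature this package follows, so the objective is surfaced
explicitly here. For ≤ 3 metrics the simplex is searched densely (step
0.05); for more, 2000 seeded Dirichlet draws are followed by
best-improvement coordinate refinement (steps 0.1 → 0.01). Candidate
streams are keyed by a content hash of each input matrix, so permuting the
inputs permutes every candidate in lockstep and the optimal value is
exactly permutation-invariant.

## Graph-theoretical metrics

Implemented directly (`connrepro.metrics`) with path length = 1/weight, the
dominant convention for connectivity-strength weights:

* **degree** — binary degree of the support ("degree" is taken at face
  value; strength, the weighted analogue, is computed but reported
  separately);
* **clustering** — Onnela's weighted form (geometric mean of triangle
  weights, pre-scaled by the graph maximum), one convention among several
  for weighted clustering; flagged as a choice, not a given;
* **local efficiency** of node i — global efficiency of the subgraph
  induced on i's neighbours;
* **betweenness** — Brandes' algorithm on 1/weight lengths with fractional
  credit for ties, reported unnormalised in the unordered-pair convention
  (the ordered-pair sum halved);
* **global efficiency** — mean inverse shortest-path length over ordered
  pairs (0 when unreachable); **characteristic path length** — mean length
  over *reachable* ordered pairs (an edgeless graph has GE 0 and CPL NaN
  with a warning). The harmonic-mean variant of CPL is deliberately not
  used, since GE already covers it.

On max-1-normalised graphs all of these are scale-free; the test suite
asserts both the raw scaling laws and the normalised invariance, and checks
every metric against brute-force path enumeration on small graphs.

## Reproducibility statistics

* **Graph similarity** — cosine of the N(N−1)/2-vectors of unique-pair
  weights (zeros for absent edges), which is equivalent to concatenating
  each graph's edges with zero padding; bit-identical graphs return
  exactly 1 so that degenerate zero-variance cohorts are detected exactly.
* **Topology similarity** — fraction of unique pairs whose supports agree.
* **Absolute fractional difference** — |w₁−w₂|/((w₁+w₂)/2) ∈ [0, 2];
  exactly 2 iff the edge is present in exactly one scan; undefined (and
  excluded upstream) when absent from both. Fractional-difference
  summaries use all edges present in at least one scan, independent of ICC
  eligibility.
* **ICC** — ICC(A,1): two-way random effects, absolute agreement, single
  measurement, computed from the participant × scan ANOVA decomposition;
  it can be negative, and is undefined (missing, with a warning) for
  constant data. Edge ICCs require the edge in both scans of at least
  ⌈P/3⌉ participants (= 12 at P = 37) and at least 3 usable participants.
  The one-third rule generalises the real-cohort convention; the A,1 form
  is the standard test-retest choice when the scan session is a random
  facet, and is a parameter of the function.
* **GLM of edge reliability** — OLS of the z-scored absolute fractional
  difference on 18 z-scored predictors (nine scan-1 attributes, nine
  absolute between-scan attribute differences), pooled jointly over
  participants and edges so coefficients are comparable across predictors;
  constant and aliased columns are dropped via pivoted QR with a warning.
  Note that NS and PS are nearly collinear by construction (PS is
  normalised NS), which inflates their individual coefficients; the FDR
  flags and R² are unaffected.
* **Attribute tests** — Welch two-sample t-tests comparing each attribute
  between edges present in both scans and edges present in one, BH-FDR
  across the nine attributes.
* **Strongest edges** — per pair, the sum over participants of weights at
  or above 0.9 (graphs are max-1), ranked descending with lexicographic
  tie-breaks.
* **Distribution comparisons** — paired t-tests between schemes (per
  b-value) or between b-values (per scheme), BH-FDR at q = 0.01;
  identical paired samples yield an undefined t reported as
  non-significant; participants missing from either arm are dropped with a
  warning.

## Power

Q = √N·μ/σ, and the required-N multiplier between two schemes is the
squared ratio of their SDs (sample SDs, n−1 denominator). The reference
scheme defaults to the one with the smallest SD; a zero-SD reference is a
hard error naming the scheme, because a degenerate distribution admits no
meaningful ratio. Report rounding is one decimal, half-up.

## Problem sizes and defaults

The shipped study conditions are `n_participants=10`, `n_nodes=90`,
`density=0.35`, `retest_correlation=0.9`, `dropout_rate=0.2`,
`ns_tail_exponent=2.0`, `md_cv=0.05`. The heaviest stage is nine-metric
integration (a few seconds per unique matrix set at 90 nodes with the
default 2000 draws); the pipeline memoises constructed graphs by content
hash, so bit-identical scans — e.g. the zero-noise cohort — are built once.
Unit tests run on 12–30-node cohorts, where every property is equally
binding, and reserve the 90-node configuration for the end-to-end
zero-noise study.

## Known limitations

* The integration objective is a stated stand-in for a loosely specified
  step; coefficient *values* should not be compared against other
  implementations, though the integrated graphs are well-defined and
  reproducible here.
* Synthetic inter-b-value structure is not modelled: cohorts generated
  with different labels/seeds are statistically independent, so the
  inter-b comparison mode exercises the plumbing, not realistic
  cross-weighting agreement.
* The GLM is a pooled fixed-effects model; participant-level random
  effects are out of scope.
* Betweenness tie handling assumes exact float equality of path lengths,
  which is the right semantics for the discrete tie structures that occur
  in practice (unit-weight motifs) but can split near-ties arbitrarily on
  pathological inputs.
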