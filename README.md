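# connrepro

Graph-construction schemes for structural brain networks: test-retest
reproducibility and the power of connectome studies.

## The problem

Structural brain networks are built from diffusion-MRI tractography: the 90
cerebrum regions of the AAL atlas become nodes, and the white-matter tracts
linking them become weighted edges. But "the" structural connectome depends
heavily on the *graph-construction scheme* — which tract metric weights the
edges (number of streamlines NS, fractional anisotropy FA, mean diffusivity
MD, or a data-driven combination of nine metrics), and which rule defines
the topology (an absolute threshold on edge weights, or Orthogonal Minimal
Spanning Trees, a data-driven filter). Schemes differ in how reproducible
their graphs are across a scan-rescan interval with no true anatomical
change, and that reproducibility directly determines how many participants
a longitudinal or case-control study needs.

`connrepro` implements this whole comparison pipeline for anyone planning a
structural-connectome study: it builds graphs under twenty registered
schemes, quantifies reproducibility at the level of whole graphs,
topologies, individual edges and graph-theoretical metrics, and converts
metric variability into required sample sizes. A synthetic cohort generator
with the statistical structure of real tractography data (heavy-tailed
streamline counts, near-uniform MD, covarying metrics, calibrated scan-scan
correlations, preferential dropout of weak connections) makes every stage
testable without imaging data.

## The core methods

**OMST topological filtering.** Successive minimal spanning trees are
extracted under edge length 1/weight, each round orthogonal to (reusing no
edge of) the previous rounds. The union of the first *m* trees is scored by

    J(m) = GE(U_m) − Cost(U_m)

with GE the weighted global efficiency and Cost the retained fraction of
total edge weight; the returned topology maximises J. The result is
connected and threshold-free.

**Diffusion-distance metric integration.** The distance between two graphs
is max over diffusion time t of ‖exp(−tL_A) − exp(−tL_B)‖_F, with L = D − W
the graph Laplacian. An *integrated* graph is the simplex-weighted linear
combination Σ_k α_k M_k of single-metric graphs minimising the summed
diffusion distance to each input.

**Sparsity-matched thresholding.** Threshold schemes keep the top-K edges
by weight, with K set so the graphs match the cohort-mean sparsity of the
nine-metric OMST graphs; the retained edges are optionally re-weighted by a
different metric (e.g. NS selects the edges, FA weights them).

**Reproducibility statistics.** Graph similarity is the cosine of the two
unique-edge weight vectors; topology similarity the fraction of node pairs
whose supports agree; edge reliability uses the absolute fractional
difference |w₁−w₂|/((w₁+w₂)/2) ∈ [0, 2] (exactly 2 for an edge seen in only
one scan) and ICC(A,1) for edges present in both scans of at least a third
of the cohort; a standardised GLM relates edge reliability to the nine
tract attributes; paired t-tests with Benjamini–Hochberg FDR compare
schemes and diffusion weightings.

**Power.** For two normal populations with mean difference μ, common SD σ
and N participants per group, Q = √N·μ/σ sets the power; holding Q fixed,
switching to a scheme with SD ratio r multiplies the required N by r².

## Worked example

```python
from connrepro import SyntheticConfig, generate_cohort, run_study

config = SyntheticConfig(n_participants=8, n_nodes=90, retest_correlation=0.9,
                         dropout_rate=0.2, seed=1)
cohort = generate_cohort(config)

study = run_study(cohort, scheme_ids=("NS-OMST", "NS-thr", "NS-t/FA-w"), n_draws=400)

print(study.similarity_records.groupby("scheme")[
    ["graph_similarity", "topology_similarity"]].mean().round(3))
print("reference sparsity (mean 9m-OMST):", round(study.reference_sparsity, 4))
print(study.power_graph_similarity.round(3))
```

prints

```
           graph_similarity  topology_similarity
scheme
NS-OMST               0.873                0.982
NS-t/FA-w             0.626                0.968
NS-thr                0.880                0.968

reference sparsity (mean 9m-OMST): 0.0431

              sd  sd_ratio  required_n_multiplier
scheme
NS-OMST    0.103     1.120                  1.254
NS-t/FA-w  0.033     0.364                  0.132
NS-thr     0.092     1.000                  1.000
```

Read: on this synthetic cohort the NS-thresholded scheme reproduces whole
weighted graphs best (mean scan-rescan cosine similarity 0.880), while the
NS-OMST scheme reproduces the *topology* best (0.982) — its data-driven
filter keeps a sparser, more stable edge set (the thresholded schemes were
matched to the nine-metric OMST sparsity of 0.0431). The power table
converts each scheme's graph-similarity SD into the factor by which a
study's sample size must grow, relative to NS-thr, to detect the same
effect: e.g. choosing NS-OMST here would require 1.25× the participants.
The same machinery runs from the shell:

```bash
connrepro synth --participants 8 --nodes 90 --seed 1 --out cohort/
connrepro repro --manifest cohort/manifest.csv \
    --schemes NS-OMST,NS-thr,NS-t/FA-w --out reports/
connrepro power --sd NS-thr=0.008 --sd NS-OMST=0.021 --reference NS-thr
```

`reports/` then holds CSV tables: per-scheme similarity means/SDs, the
between-scheme similarity matrix, edge-ICC summaries, GLM coefficients,
strongest edges per scheme (with AAL region names), and SD ratios with
required-N multipliers.

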