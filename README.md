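# lineagescope

Condition-comparison analyses for branching haematopoietic single-cell
RNA-seq experiments with replicate animals.

The package is aimed at the analysis stage that follows clustering in a
perturbation study of mouse HSPCs — e.g. comparing drug-treated against
vehicle-treated bone marrow with a handful of mice per arm. It implements,
as tested and reusable code:

* **differential cluster abundance** — per-sample cluster fractions, independent
  t-tests, BH correction (flagged at adjusted p < 0.2);
* **gene-signature scoring** (e.g. a defense-to-virus / dsRNA-response
  score) against expression-matched control genes, with per-cluster
  condition tests, and transcriptomic **cell-cycle phase assignment**
  (G1 iff both S and G2M scores are negative);
* **seven-lineage cell-fate probabilities**: absorption probabilities of a
  pseudotime-directed absorbing Markov chain on the kNN graph, with
  per-cluster condition comparisons;
* **sliding-window pseudotime statistics** — per-sample label fractions in
  overlapping windows (width 0.01, step 0.0025), t-tests with BH per
  label, a significance track at adjusted p < 0.05;
* **trajectory-resolved differential dynamics** — condition-specific cubic
  B-spline smoothers with a nested-model F-test — and **pseudobulk
  condition DE** with median-of-ratios normalisation;
* a **synthetic branching-haematopoiesis generator** (3 + 4 replicate
  design, HSC-rooted lineage tree with seven terminal lineages, negative
  binomial counts) with injectable condition effects — fate bias,
  a G1/quiescence shift over a pseudotime interval, a signature
  fold-change, and a global DE block — so every stage is exercisable and
  testable without any external download.

The core fate model: for non-terminal cell *i* with kNN neighbours *j*,

    w_ij = exp(β · clip(t_j − t_i, ±s)/s) / Σ_j' exp(β · clip(t_j' − t_i, ±s)/s)

a softmax over pseudotime increments (s = 1 gives the plain softmax; the
pipeline uses s = median |Δt|, which saturates the directionality one
neighbour-step away). Terminal cells — the high-pseudotime tips of the seven
lineage clusters — are absorbing, and fate probabilities B solve
(I − Q)B = R for the transient block Q. See `docs/methods.md` for the full
model description, assumptions and limitations.

## Worked example

```yaml
# config.yaml
seed: 1
output_dir: out
stages: [simulate, preprocess, phase, score, abundance, fate]
simulate: {preset: paper_like}     # 3+4 samples x 1000 cells, 2000 genes
```

```
lineagescope run -c config.yaml
```

writes one TSV per stage plus a JSON run log. The per-cluster signature
comparison (`out/signature_cluster_tests.tsv`) shows the injected
inflammatory signature recovered as upregulated in the treated condition in
every cluster:

```
cluster  mean_treated  mean_vehicle  difference  p_adj
    CLP        0.1325       -0.1135      0.2460    0.0
    GMP        0.1275       -0.1134      0.2409    0.0
    HSC        0.1988       -0.0693      0.2681    0.0
    MEP        0.1423       -0.1161      0.2584    0.0
    ...
```

(scores are mean log-normalised expression of the 50 signature genes minus
matched controls; the ~0.25 gap reflects the injected 0.5 log2
fold-change). The fate comparison (`out/fate_cluster_tests.tsv`) recovers
the injected erythroid fate bias at the MEP level:

```
cluster    lineage  mean_treated  mean_vehicle      p   p_adj
    MEP  erythroid        0.3961        0.6717 0.0000  0.0000
    HSC  erythroid        0.1996        0.1510 0.0000  0.0000
```

— the treated cohort's erythroid fate probability in the MEP cluster is
depressed (injected 0.46 vs 0.56). Estimates from a single 7,000-cell
replicate are noisy (±0.05–0.1 per cluster mean); the acceptance script
below reports medians over 20 replicates, which recover the injected values
to within ±0.05.

The same stages are available as library calls (`simulate_experiment`,
`preprocess_dataset`, `run_fate`, `run_windows`, …) on a `Dataset` of
MatrixMarket counts plus cell/gene TSV tables.

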