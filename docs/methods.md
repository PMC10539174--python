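# Methods

`lineagescope` implements the replicate-aware condition comparisons that a
perturbation scRNA-seq study of mouse haematopoietic stem and progenitor
cells (HSPCs) runs after clustering: differential cluster abundance,
gene-signature scoring and cell-cycle phase calls, seven-lineage cell-fate
probabilities, sliding-window pseudotime statistics, and trajectory-resolved
differential gene dynamics. This note describes the models, their
assumptions, the defaults that matter, and what the synthetic data generator
does and does not emulate.

## Data model

Counts are cells × genes everywhere in memory; on disk the MatrixMarket file
is genes × cells (the common public convention) and the reader transposes.
Cells carry `sample_id` (replicate animal) and `condition` (one of a
declared label pair, default `STM2457` / `Vehicle`). Every comparison in the
package is a two-tailed t-test plus Benjamini–Hochberg (BH) correction over
an explicitly stated family: the replicate-level tests (abundance, windows,
pseudobulk; 3 vs 4 samples) use the pooled-variance independent t-test,
because at these group sizes the Welch–Satterthwaite approximation is
measurably conservative (type-I rate ~0.040 at nominal 0.05 even on normal
data), while the per-cell tests (signature scores, fate probabilities),
where groups are large and variances can differ, use Welch. Zero-variance-
in-both-groups comparisons with equal means get p = 1 by convention.

## Synthetic experiments

The generator emulates the structure of the motivating study: LK HSPCs from
3 treated and 4 vehicle animals, a lineage tree rooted at HSCs with seven
terminal lineages (neutrophil, monocyte, lymphoid, erythroid,
megakaryocyte, basophil, mast), and four injectable condition effects. The
default tree is

    HSC → MPP → {GMP, MEP, CLP}
    GMP → {neutrophil, monocyte, basophil, mast}
    MEP → {erythroid, megakaryocyte};  CLP → {lymphoid}

with the CLP node added so that every root→leaf path has four nodes and the
equal-split pseudotime intervals that define the ground-truth cluster labels
agree across paths on shared segments.

Per cell: a terminal lineage is drawn from a condition-specific fate prior,
pseudotime t ~ Uniform(0,1), and a cycle phase from pseudotime-dependent
proportions. The default fate priors are anchored on the reported
cluster-mean fate probabilities of the study this design mirrors: marginal
erythroid 0.12/0.15 and neutrophil 0.16/0.12 (treated/vehicle), with the
megakaryocyte prior solved so the erythroid share of the MEP branch is
0.46/0.56; the remaining mass is split over monocyte/lymphoid/basophil/mast
with fixed weights 0.25 : 0.20 : 0.08 : 0.05 (a simulator convention — the
study reports no values for these).

Expression: each tree node owns a block of 30 program genes whose log2
effect ramps linearly from the start of the *parent* interval to the end of
the node's own interval (saturating at 2.5). The one-node-early "priming"
makes sibling corridors transcriptionally separable before their cluster
boundary, which is what real, clusterable data look like. Cycle phases add
40-gene S and G2M programs (log2 FC 1.0); treated cells additionally carry a
50-gene inflammatory-signature shift (log2 FC 0.5) and a global DE block of
150 up / 90 down genes at log2 FC 0.8 (counts echo the scale of the study's
152/89 DE genes). Gene means are baseline (LogNormal(0,1) relative
abundance) × 2^(active effects), renormalised per cell and scaled by a
LogNormal(ln 5000, 0.35) library size; counts are negative binomial with
var = μ + αμ² (α = 0.1; α = 0 switches to Poisson). All latent variables and
gene-block memberships are exported (`true_*` cell columns, gene flags) for
parameter-recovery tests.

The `null` preset removes every condition effect (shared averaged priors, no
G1 shift, zero signature fold-change, no DE block) and underlies the type-I
error tests. Not emulated: doublets, ambient RNA, batch effects within
condition, UMI-level noise. Consequently, passing recovery tests show the
statistics behave correctly on clean branching data of this size, not that
they are robust to those artefacts on real data.

## Preprocessing and pseudotime

Each cell is scaled to 10,000 counts and log1p-transformed; the top 600
genes by variance of the normalised values (ties broken by gene id) enter a
30-component PCA (exact SVD, deterministic sign convention). kNN graphs are
exact Euclidean k = 40 neighbour lists with index-order tie-breaking.

Because the package performs no batch integration (out of scope), the two
conditions form offset sheets in the embedding. The pipeline therefore
builds the kNN graph *within each condition*; the graph is then
multi-component by construction, each component is rooted at its earliest
cell (minimal `true_pseudotime` on simulated data; user-supplied roots on
real data), and pseudotime is the shortest-path geodesic distance from the
component root over the symmetrised weighted graph, normalised to [0, 1]
within each component. This is a deliberate simplification — deterministic,
dependency-free and monotone along simulated branches (Spearman ρ vs truth
> 0.9 per condition at the default design) — not a re-implementation of any
published pseudotime method.

## Cell-fate probabilities

Terminal macrostates: for each of the seven lineages, the cells of its
terminal cluster with pseudotime at or above the 0.9 quantile, taken within
cluster × condition (so an embedding offset between unintegrated conditions
cannot exclude one condition's tip).

Transitions: from a non-terminal cell i to each kNN neighbour j with weight
softmax over pseudotime increments, w_ij ∝ exp(β · clip(t_j − t_i, ±s) / s).
With s = 1 (and pseudotime in [0, 1]) the clip is inactive and this is the
plain softmax over increments. The pipeline default is the adaptive scale
s = median |Δt| over kNN edges: the raw increments are O(10⁻³), at which the
unscaled softmax with β = 5 is nearly undirected, while an *unclipped*
scaled softmax overweights the furthest-ahead neighbour and funnels walkers
into sparse corridors. The saturating form makes the walk step almost
uniformly among forward neighbours and suppress backward steps by e^{2β},
keeping branch splits proportional to corridor cell density. β defaults
to 5. Terminal cells are absorbing.

Fate probabilities solve the absorbing-chain system (I − Q)B = R by direct
sparse LU factorisation (deterministic and exact at these sizes; an
iterative solver is unnecessary), with absorption mass summed over each
lineage's terminal cells. Row sums are validated to 1 within 1e-8; cells
with no path to any terminal cell are an error. Per-cluster condition
comparisons are Welch t-tests on per-cell fate probabilities, BH-corrected
across all (cluster, lineage) pairs — per-cell rather than per-sample,
matching the magnitude of the p-values such studies report for per-cell
quantities.

At the default design (7,000 cells, 2,000 genes, 20 replicate simulations)
the pipeline recovers the injected cluster-mean fate probabilities with
median error ≤ 0.04. The replicate-to-replicate spread of a single
cluster-mean estimate is ±0.05–0.1 — graph-geometry noise that does not
average out within one replicate — so the *direction* of the small HSC-level
contrasts (0.03–0.04) is reproduced in only ~60–90% of individual
replicates at this scale. A ~50k-cell experiment, as in the motivating
study, is needed before per-replicate signs stabilise; this is a known
limitation of the desk-scale design, not of the estimator's median.

## Signature scores and phase calls

A signature score is the mean log-normalised expression of the signature
genes minus the mean over control genes drawn from expression-matched bins:
genes are ranked by dataset-wide mean expression and cut into 25 equal-size
bins, and 50 controls per signature gene are drawn from its bin (excluding
signature genes) with a per-gene seeded RNG stream, which makes scores
invariant to signature order and to absent genes. Cluster-level condition
comparisons are per-cell Welch t-tests, BH across clusters.

Phase assignment scores an S and a G2M gene list the same way and calls G1
iff both scores are negative, otherwise the phase of the larger score.
Default mouse S/G2M lists (the widely used cell-cycle marker sets) ship as
data files and are overridable; on simulated data the simulator's own
S/G2M program genes are used. The matched controls are what give G1 cells
negative scores: cycling cells inflate the dataset-wide mean of cycle
genes, so their bin-matched controls sit higher than the G1 cells' baseline.

## Differential abundance

The tested unit is the per-sample cluster fraction (fractions over clusters
sum to 1 per sample). Per cluster: pooled t-test treated vs vehicle on the
per-sample fractions, BH across all clusters tested in the run, flagging at
adjusted p < 0.2. Clusters under 20 cells are excluded before correction
(a fraction-of-dataset rule, e.g. 2%, is available as an option).
Fractions are tested untransformed; no compositional (log-ratio) transform
is applied in v1 — a documented limitation, as a strong change in one
cluster necessarily moves the others.

## Sliding-window statistics

Windows of width 0.01 advance in steps of 0.0025 (397 windows on [0, 1]);
each window is [start, start + width), the last closed at 1. Within a
window, each sample contributes the fraction of its in-window cells carrying
each label (missing if it has fewer than 10 cells there); per (window,
label) the conditions are compared by pooled t-test over per-sample fractions
when both have ≥ 2 non-missing samples, and BH runs within each label over
its tested windows (the G1 family separate from S, a declared choice).
Significance is adjusted p < 0.05. "Along the erythroid trajectory" is made
reproducible by restricting to cells whose erythroid fate probability
exceeds 0.5 (shared with the trajectory DE stage). BH controls the false
discovery *rate*, so with hundreds of true-effect windows a few false
positives among null windows are expected behaviour of the procedure.

## Trajectory differential dynamics and pseudobulk DE

Per gene, log-normalised expression along pseudotime is fitted by least
squares on a clamped cubic B-spline basis (6 interior knots at pseudotime
quantiles of the trajectory cells), the identical basis for both
conditions; a nested-model F-test compares one shared curve against
condition-specific curves, F = ((RSS₀ − RSS₁)/p) / (RSS₁/(n − 2p)), BH
across genes at α = 0.05. Gaussian least squares on log values replaces the
negative-binomial GAM a dedicated trajectory-DE package would fit — a
deliberate, closed-form, testable simplification. With an intercept-only
basis the test reduces exactly to one-way ANOVA.

Pseudobulk DE sums counts per sample and normalises by median-of-ratios
size factors (genes detected in every sample against their geometric mean)
rather than raw totals: at desk scale the injected DE block is a fifth of
the gene panel, and total-count scaling would shift every unchanged gene in
the opposite direction (composition artifact). A per-million constant keeps
values invariant to global depth changes. Per gene: pooled t-test across
samples on log2 values, BH, direction by sign of the mean difference;
all-zero genes get p = 1.

## Determinism and problem sizes

Every stochastic step (simulation, control-gene draws) is governed by
explicit seeds; embeddings, solvers and tie-breaks are deterministic, and
re-running a pipeline config with the same seed reproduces byte-identical
result tables. The test-suite and acceptance problem sizes — 7,000-cell
experiments, 20 replicates for fate recovery, 50 replicates for type-I
calibration, 10,000 latent cells per sample for window recovery — were
chosen as the smallest designs at which the assertions are statistically
meaningful.
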