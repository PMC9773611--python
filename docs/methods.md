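# Methods

This note documents the models, defaults, and numerical conventions behind
`tmekit`, and what the synthetic validation does and does not demonstrate.

## Quality control

Per cell: detected genes (count > 0), total UMI, and mitochondrial fraction
(mito UMI / total UMI, defined as 0 for an empty cell). A cell is kept when
`min_genes <= genes <= max_genes`, `min_umi <= umi <= max_umi`, and
`mito_frac < max_mito`. Defaults 200–7500 genes, 500–75,000 UMI, mito < 0.10.
Range bounds are inclusive and the mitochondrial cap strict; this convention
is fixed and exercised by a boundary fixture in the tests. Filtering is
idempotent and touches cells only — no gene filtering happens at this stage.

## Normalization

Counts are scaled per cell to a common target depth (default: the median
post-QC depth) and log1p-transformed. This is a deliberate simplification of
regularized-NB residual approaches: every downstream consumer here (variable
gene selection, PCA, rank-based DEG tests, affinity products, cluster-mean
profiles) only requires a depth-invariant, monotone, zero-preserving
transform, which this is. The method name and any removed components are
recorded in `uns["provenance"]`. A zero-depth cell is an error (it cannot
occur after QC).

## Dissociation-artifact removal

Enzymatic dissociation can induce a stress/heat-shock program whose strength
varies by sample. FastICA (scikit-learn, unit-variance scores, fixed seed,
deterministic sign convention: each gene-loading vector's largest-magnitude
entry is positive) decomposes the normalized matrix; each component is scored
by the variance of its per-sample mean cell score over the pooled
within-sample variance. The artifact is the top-scoring component when it
exceeds median + 5·MAD of all component scores — a robust stand-in for the
by-inspection selection a human would do; the statistic and cutoff are
configurable. Removal subtracts the component's rank-one term
`scores[:,k] ⊗ loadings[:,k]`, leaving all other components' projections
unchanged and commuting with cell subsetting.

The number of components defaults to 128, appropriate for genome-wide
matrices. The bundled synthetic cohorts have only a few hundred genes, so
their analyses and the validation studies use 32 components; the artifact
program is rank one, so recovery does not depend on this choice once the
component count comfortably exceeds the number of planted structures.
FastICA may stop at `max_iter` without formal convergence on near-degenerate
components; this is reported as a warning with the iteration count and does
not affect the separated artifact component in practice.

## Stepwise clustering

Round one: top-1000 variance genes (ties broken by gene identifier), PCA to
100 components (deterministic full SVD, sign-fixed), a batch-balanced kNN
graph, and Leiden (RB-configuration quality, fixed seed, run to convergence).
The balanced graph connects each cell to its `k_within = 3` nearest Euclidean
neighbors within *each* chemistry batch and symmetrizes the union, so no
batch can form its own cluster neighborhood. Fine first-round clusters are
merged into major populations by a canonical-marker map (name → marker genes;
each cluster takes the name whose markers it expresses highest) — the
config-driven equivalent of curated cluster merging. Round two repeats the
pipeline inside each major (600 genes, 25 components by default; majors under
100 cells are skipped) with minor ids namespaced by the major id.

Resolution defaults are 1.0 for both rounds. For the bundled synthetic
cohorts the subclustering step uses resolution 0.3: their major clusters hold
only one-to-two hundred cells, and at resolution 1.0 an unweighted ~6-degree
kNN graph of that size fragments homogeneous groups; 0.3 resolves the planted
subtypes without fragmentation. Per-population resolutions on real data
remain an analyst's choice, as they are in practice.

Differential expression is one-vs-rest Wilcoxon rank-sum per gene
(tie-corrected normal approximation via scipy, vectorized over genes) with
BH adjustment within each cluster's scan; Holm-adjusted values are computed
alongside for marker ranking. A gene is a DEG of a cluster when adjusted
p < 0.05, over 30% of the cluster's cells express it, and it is upregulated
(positive fold change) — without the sign requirement, a marker of one
cluster would also qualify as a "DEG" of every cluster where it is
significantly *absent*. Fold change is computed on expm1 of the group means
with a 1e-9 pseudocount. Top markers rank by descending fold change, then
ascending Holm p, then gene id. Low-quality clusters are those combining a
median detected-gene count at or below 250 with zero unique DEGs, plus any
cluster whose median mitochondrial fraction exceeds the QC cap.

## Cell–cell communication

Pair affinity between cells is the product of ligand expression in one cell
and receptor expression in the other; total affinity sums both directions
over the pair database (duplicates dropped by default). The matrix is bilinear
in the two cells' expression vectors, so it factors into two cells×pairs
blocks; all computation runs on those factors and the dense cell×cell matrix
is only materialized below a configurable cap (default 5000 cells) — above
it, neighbor search streams over row blocks.

The neighbor graph takes each cell's k = 15 *highest-affinity* partners
(ties broken toward lower cell index, self excluded, union-symmetrized).
Cluster-pair connectivity is the graph-abstraction statistic: observed
inter-cluster edge count divided by its expectation
`E_total · n_M n_N / C(n,2)` under random edge placement; pairs above 0.05
are significant. Closeness centrality is computed on the significant-edge
subgraph with edge length 1/connectivity as
`(reachable−1) / Σ shortest-path lengths` per connected component (isolated
clusters score 0), ranked descending with ties by cluster id. Per-pair mean
affinity between clusters M→N reduces to
`mean_M(E_ligand) · mean_N(E_receptor)`; contributions normalize these to
sum to one, with a 0.01 reporting threshold.

A curated human ligand–receptor table (~150 literature-standard pairs across
chemokine, cytokine, WNT/Notch, growth-factor, integrin/matrix, checkpoint,
and adhesion families) ships with the package and is user-replaceable via
`load_lr_pairs(path)`; synthetic cohorts carry their own generated tables.

## Bulk ↔ single-cell integration

Cluster profiles are per-cluster arithmetic means of normalized expression,
z-scored per gene across clusters (ddof = 1; constant genes map to an
all-zero row). Gene bi-clustering is agglomerative with 1 − Pearson distance
and average linkage — a standard pairing for z-scored expression profiles and
invariant to row scaling; constant rows are assigned distance 1 to
everything. The tree is cut at a user-chosen number of modules and labels are
renumbered by dendrogram leaf order, making the assignment deterministic and
input-order invariant. Up- and downregulated gene lists are meant to be
clustered in separate runs. The number of modules is never auto-selected.

Robustness: per repetition, a fraction (default 90%) of the target cell
type's cells is removed at random, the profile and bi-clustering recomputed,
new modules matched to the originals by maximal-overlap Hungarian assignment
(well-defined even when module counts drift), and each gene scored as
preserved when its new label maps back to its original one. The validation
study uses 20 repetitions — a desk-scale version of the same design at 100.

## Cohort statistics

Abundance: samples under 200 cells are excluded; in lineage-restricted runs,
samples with under 50 cells of the lineage are excluded from that lineage
and percentages renormalize within it (always re-summing to 100 per sample).
Tumor-vs-normal tests are Wilcoxon rank-sum on per-sample percents (paired
signed-rank across patients with both tissues as an option), Holm-corrected
across clusters. The displayed effect is log2 of mean percents with a 0.1
percentage-point pseudocount so tumor-exclusive populations stay finite.

Rank tests use exact enumeration for group sizes up to 8 — all C(n₁+n₂, n₁)
group assignments (or 2ⁿ sign flips, paired), valid under ties; the two-sided
p counts assignments at least as far from the null mean as observed, which is
exact by the symmetry of the permutation distribution. Larger groups use the
tie-corrected normal approximation.

Signature scores are rank-based: genes ranked per unit by descending
expression (average ties), ranks clipped at `max_rank + 1` (default
max_rank 1500, the convention of rank-based single-cell scoring tools;
signature genes missing from the expression space take the clipped worst
rank), and the Mann–Whitney U of the signature ranks mapped to
`1 − U/(n_sig · max_rank)` ∈ [0, 1]. The score depends on the expression
vector only through its ranking, hence is invariant to monotone transforms
and applies unchanged to single cells and bulk samples. AUROC is U/(n₁n₂)
with average-rank tie handling plus a sweep of sensitivity/specificity at
every observed threshold.

## Synthetic cohorts

Counts are Gamma–Poisson (negative binomial, shared dispersion θ = 2) with
per-gene lognormal baseline means around 3 — at 300–400 genes this places
cells at ~250 detected genes and ~1300 UMIs, inside the QC window, so default
cohorts survive filtering intact. Planted structure is additive on the
log2-mean scale: disjoint marker blocks per major type and per minor subtype
(log2 effect 3), a stress block elevated in designated samples, and
ligand–receptor genes shifted in their sender/receiver clusters.
Ligand/receptor genes carry a low off-target baseline (mean 0.25), reflecting
lineage-restricted receptor expression; every cluster in the communication
preset has an autocrine pair (log2 effect 5) so cells neighbor their own
cluster by affinity, and the hub's five paracrine axes use effect 6. Sample
composition is Dirichlet-multinomial (concentration 100–150) so per-patient
composition varies realistically; tumor-enriched clusters are set to
fold-change × base proportion with the remaining mass renormalized over the
other clusters, making the planted percent ratio exact in expectation. One
master seed drives fixed-offset PCG64 child streams per stage
(`SEED_OFFSETS`), so cohorts are bit-identical across runs and platforms.

Preset study conditions: clustering (6 patients × 2 tissues × 100 cells,
3 majors × 2 subtypes), communication (8 clusters × ~100 cells, 1 hub,
5 axes, 4 decoy pairs), artifact (6 samples, 50 stress genes elevated in 2
samples, effect 2.5), abundance (10 tumor + 10 normal × 250 cells, one
cluster at 4% normal / 20% tumor), bulk integration (5 programs × 20 marker
genes). These sizes keep each 100-seed validation study in tens of seconds
on one CPU.

What the generator does **not** emulate: doublets, ambient RNA, gene–gene
correlation beyond the planted modules, batch effects on expression (batches
differ only in labels), TCR/clonal structure, or realistic gene-length/GC
biases. Passing the validation studies therefore demonstrates that each
algorithm recovers the structure it targets under clean NB noise at stated
effect sizes — not that it is robust to every artifact of real droplet data.

## Validation studies

`tmekit.evaluation` (used by the tests and `scripts/acceptance.py`)
regenerates cohorts from seeds and reports: brute-force agreement of the
affinity/contribution pipeline (quadruple-loop oracle, 50 cells × 30 pairs);
hub top-1 closeness and planted-connectivity significance over 100 seeds;
artifact top-50 loading Jaccard and post-removal residual specificity;
two-round clustering ARI ≥ 0.9 over 100 seeds; bi-clustering module ARI and
20-rep downsampling preservation; exact-enumeration agreement of the rank
tests, direct-formula agreement of Holm/BH, concordance-count agreement of
AUROC over 200 random fixtures; the QC boundary fixture; and recovery of the
planted 5-fold abundance shift (Holm p < 0.05, log2 ratio within ±0.5 of
log2 5) over 100 seeds.
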