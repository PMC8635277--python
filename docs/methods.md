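# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the synthetic-data generators the tests rely on, and the
numerical and design choices that were genuinely open.

## Bulk time-course model

The bulk pipeline operates on a gene × sample count matrix over five
ordered populations — blood monocytes (day 0), Ly6C-high infiltrating
macrophages (days 1 and 2), and Ly6C-low repair macrophages (days 2 and
4). The population order is always declared explicitly (in `RunConfig` or
per call); it is never inferred from sample-name sorting, because labels
like "Ly6C-low day 2" and "Ly6C-high day 2" cannot be ordered lexically.

**Normalization and filtering.** CPM = count / column sum × 10⁶. A gene
is retained when its *maximum population-mean* CPM is ≥ `cpm_min`
(default 10). The per-population-mean reading keeps genes that are well
expressed in any one state of the time course — the natural choice for a
design whose interesting genes turn on or off along the course. With
`coding_only`, genes whose annotated `gene_type` is not `protein_coding`
are masked with reason code `non_coding`; low-expression masking uses
`low_cpm`. Masked genes are excluded from every downstream stage.

**Differential expression.** A gene-wise negative-binomial
likelihood-ratio test, deliberately simpler than the empirical-Bayes GLM
machinery of the established bulk DE packages:

- size factors are median-of-ratios (each sample's median count ratio to
  the gene-wise geometric-mean reference over genes positive in all
  samples, falling back to column sums when fewer than 10 such genes
  exist). Total-count factors are biased when a sizable minority of genes
  changes in one direction; median-of-ratios is robust to that
  composition effect;
- dispersion is method-of-moments from pooled within-group variability
  of normalized counts, `alpha = max((s² − m)/m², 0.01)` — the 0.01 floor
  prevents near-zero variance estimates from inflating the statistic;
- the null model shares one mean across both groups, the alternative
  fits one per group; the statistic 2·(ll₁ − ll₀) is referred to χ²(1),
  clipped at zero because the group means are moment estimates rather
  than exact MLEs;
- BH step-up FDR across genes; a gene is *flagged* DE only when
  |log2FC| ≥ log2(1.5) **and** FDR < 0.05. log2FC uses a pseudocount of
  0.5 on normalized means and is oriented group-b-over-group-a.

The DE stage is pluggable: `prioritize` accepts any `DETable`, so a table
imported from an external tool can replace the built-in test.

**Trajectories.** Per gene: mean log2(CPM+1) over replicates within each
population, then z-scored across the populations (mean 0, sd 1, ddof 0).
Genes constant across populations have undefined z rows and are dropped
with a warning. Pre-scaling means and sds are retained for reporting.

**Choosing k.** The gap statistic with Tibshirani's simple reference:
B = 50 data sets drawn uniformly over each feature's observed range,
`Gap(k) = mean_b log W*_kb − log W_k`,
`s_k = sd_b(log W*_kb)·sqrt(1 + 1/B)` (population sd), and the 1-SE rule
`k* = min{k : Gap(k) ≥ Gap(k+1) − s_{k+1}}`. If the rule never fires the
largest k tried is returned with a warning. `W_k` is the best inertia of
25 k-means++ restarts; reference fits use 5 restarts, since the uniform
reference has a much smoother objective and the extra restarts only cost
time. The between-group-SS elbow curve is emitted alongside for visual
confirmation. Each (k, data/reference draw) gets an independent seed
derived from the call seed, so the procedure is reproducible.

**Clustering.** scikit-learn's k-means with k-means++ initialization,
25 restarts, tolerance 1e-6, ≤ 300 iterations; argmin ties break to the
lowest cluster index, making results deterministic under a fixed seed.
The per-gene *membership score* is the Pearson correlation between the
gene's z row and its own cluster centroid — the quantity used to shade
genes by how well they match the cluster core. Assignment optimality
(every gene nearer its own centroid than any other) is asserted in tests
on every solution.

**Trend labels.** Successive centroid differences with |d| ≤ eps
(eps = 0.1 z units) are flat; all non-flat steps positive → `monotone_up`,
all negative → `monotone_down`; exactly one sign reversal with an interior
global extremum → `transient_up`/`transient_down`; anything else,
including all-flat, → `mixed`. The boundary case |d| = eps counts as flat.
The label is invariant to adding a constant to the centroid. The
`monotone_*` clusters are the steadily changing programs the candidate
ranking targets; `transient_*` clusters correspond to single-peaked
inflammatory kinetics.

**Sample relationships.** Pairwise sample distance 1 − Spearman ρ on
log2 CPM profiles of filter-passing genes, average-linkage agglomeration.
Rank-based distances make the tree invariant to monotone transforms of
any sample's values.

## Trajectory screen

Similarity is Pearson correlation computed on the same z-scaled mean
trajectories the clustering uses. Commercial screening tools offering a
"find similar entities" feature do not publish their internal similarity
definition, so Pearson-on-z-rows is *declared* the definition here; it
is scale-free, which matches the intent of matching both trend and rate. Cutoffs:
`pass_screen` at similarity ≥ 0.9; `pass_label` additionally requires
similarity > 0.93 and mean log2(CPM+1) > 7.5 in the labeling population,
which defaults to the last ordered population (the day-4 repair state).
Output is sorted by descending similarity with alphabetical tie-breaks,
so the table is invariant to input gene order.

## Prioritization and enrichment

Candidates must be (1) DE, (2) in a target trajectory cluster, and
(3) highly expressed (max population-mean log2 CPM ≥ 7.5, reusing the
screen's labeling cutoff as the one expression threshold of the
pipeline). The composite rank, membership score × |log2FC|, is
artifact-defined: candidate tables of this kind are usually curated by
hand, and a reusable pipeline needs a deterministic total order. The product rewards
cluster fidelity and effect size symmetrically; ties break alphabetically.
The secretome flag joins membership in a named user-supplied GMT set
(e.g. a VerSeDa-derived secretome).

**Rounding conventions.** Overlap percentages round half-up to one
decimal (766/952 → 80.5). Detection fractions truncate toward zero — one
decimal per set, two decimals pooled (700/716 → 97.7; pooled
1636/1668 → 98.08). The two conventions differ deliberately — they are
the ones the worked-example tests pin down — so changing either would be
a breaking change to the reported statistics.

**Enrichment.** Upper-tail hypergeometric p = P(X ≥ overlap) with
population `background_n` (default 25,000, roughly the protein-coding
mouse genome), successes = set size, draws = query size; fold enrichment
is the observed overlap rate over its expectation; BH FDR across sets.
The p value is verified against exact combinatorial enumeration in the
tests.

## Single-cell pipeline

**QC.** Cells are removed by strict inequalities — fewer than 200 genes
detected, fewer than 1,000 UMIs, more than 5% mitochondrial UMIs
(`mt-` gene prefix, case-insensitive), or more than 30,000 UMIs
(doublet-like outliers); a cell at exactly 200 genes and 1,000 UMIs is
retained. Afterwards genes detected in fewer than 3 remaining cells are
dropped. A cell failing several rules is counted once, attributed to the
first failing rule in the order low-genes → low-UMIs → high-mito →
high-UMIs; the order is a reporting convention chosen for deterministic
bookkeeping, and retained + removed = input is asserted in tests.

**Normalization and scaling.** Counts per cell scaled to 10,000 and
log1p-transformed; each gene is regressed (OLS) on the standardized
covariates — UMI count and mitochondrial fraction by default — and
replaced by its residuals, then z-scored across cells and clipped at ±10.
Zero-variance covariates and genes left with zero residual variance are
dropped with warnings.

**Embedding and SNN clustering.** PCA on the scaled matrix (30
components by default; signs fixed by making each component's
largest-magnitude loading positive, so coordinates are deterministic).
Each cell's neighbor set is itself plus its 19 nearest cells (Euclidean
in PC space, 20 total); edges are weighted by the Jaccard similarity of
neighbor sets and pruned below 1/15. Communities are found with Leiden
optimization of the RB-configuration modularity at a resolution
parameter — the Leiden refinement of the Louvain objective, with a fixed
seed. Both algorithms satisfy the same contract here; Leiden is the
backend because it cannot produce disconnected communities.

**Resolution selection.** Cluster at each resolution in a grid, compute
the average silhouette width (ASW) in PC space (on a seeded subsample of
at most 5,000 cells when larger, since silhouette cost grows
quadratically), and take the ASW-argmax; ties break toward the smaller
resolution, and resolutions yielding a single cluster are recorded with
undefined ASW and excluded. PC space is the declared silhouette metric
space. The subsampling-robustness variant of resolution selection
(co-clustering stability across cell subsamples) is a possible extension;
ASW selection is the implemented criterion.

**Markers.** Per cluster versus rest: candidates need detection in ≥ 40%
of the cluster's cells and log2 fold change > 0.25 (cluster mean over
rest on normalized counts, pseudocount 1). The "0.25" reads the
Seurat-style `logfc.threshold = 0.25` idiom as a threshold *on* the log2
fold change — the literal alternative (a cutoff of log2 0.25 = −2) would
admit essentially every gene. Significance is a Wilcoxon rank-sum test on
log-normalized values (the standard nonparametric choice for marker
calling), BH FDR within cluster; the negative-binomial alternative can be swapped in
behind the same interface. A marker is *unique* when detected in > 85% of
its own cluster and < 35% of other cells. Clusters with fewer than 2
cells are skipped with a warning.

**Program projection.** Per cell, the mean scaled expression over a
program's detected genes; per subtype, the mean over its cells. The
detection report (fraction of each program's genes present post-QC, per
set and pooled) uses the same `detection_fraction` conventions as the
bulk stage.

## Regulon activity

A regulon is a transcription factor plus its direct targets, supplied as
one GMT line per TF (regulon *inference* is out of scope). The regulator
is included in its own target set for scoring by default (switchable).

**Scoring.** Rank a cell's genes by descending expression, ties broken by
a per-cell permutation keyed on (seed, barcode) so the score is
deterministic and invariant to cell order. With k = ceil(top_fraction ×
n_genes) (top_fraction 0.05, the conventional top-5% cutoff), the
recovery curve r(i) counts regulon genes at rank ≤ i; the score is
Σᵢ r(i) normalized by its maximum (regulon occupying ranks 1..m), giving
an AUC in [0, 1]. Rank-based scoring makes the AUC invariant to any
strictly monotone transform of a cell's expression values.

**Binarization.** A two-component 1-D Gaussian mixture (EM, 3
initializations, seeded) is fit to each regulon's AUC distribution; the
threshold is the density-crossing point between the component means. When
no crossing exists between the means (heavily overlapping components),
the fallback is mean + 2 sd of the lower component. A degenerate
(constant) distribution yields all-off with a +inf sentinel. Cells are
"on" at AUC ≥ threshold; fitting on sorted values makes the threshold
order-invariant. Published regulon-activity workflows rarely state
their top-rank cutoff or binarization rule; both choices here are
declared defaults.

## Synthetic data

The generators define the conditions under which the pipeline is tested;
they are fixed, not tuned per run.

**Bulk.** Seven trajectory archetypes over the five ordered populations,
shipped as fixed constants (log2-fold units):

| archetype | centroid |
|---|---|
| monotone_up | −2, −1, 0, 1, 2 |
| monotone_down | 2, 1, 0, −1, −2 |
| transient_up_early | −1.5, 2, 0.5, −0.5, −0.5 |
| transient_up_mid | −1.5, 0, 2, 0.5, −1 |
| transient_down_mid | 1.5, 0, −2, −0.5, 1 |
| early_step_up | −2, 0.8, 1, 1.1, 1.2 |
| late_step_down | 0.6, 0.6, 0.5, 0.4, −2 |

All archetypes have genuine dynamics — two steady and five
transient/step shapes, mirroring the observed mix of steadily changing
and single-peaked clusters; a flat archetype would be unrecoverable after
z-scaling (its z rows are pure noise) and is deliberately absent.
Pairwise Pearson of the z-scaled centroids stays below 0.8 (asserted in
tests); `early_step_up` is the designated look-alike of `monotone_up` at
r ≈ 0.78. Per gene: baseline mean 2^U(4,10) counts, population mean =
baseline × 2^(centroid + N(0, noise_sd)) with independent jitter per
population, counts NB(mean, dispersion 0.1) — variance mean + 0.1·mean².
Two genes named `Igf1` and `Gdf15` are planted on `monotone_up` as the
benchmark growth factors. `dispersion=0` gives the Poisson limit and
`exact=True` returns expected counts (noise-free limit). Defaults
(100 genes/archetype, 3 replicates, noise_sd 0.2) are the recovery test
conditions.

**Single cell.** Six cell types — four macrophage-like
(resolution-phase, growth-factor/GFEM-like, inflammatory,
antigen-presenting) plus T cells and neutrophils — at 60 cells per type
by default, 400 genes. Each type has 8 exclusive markers (10-fold up in
its own type, 50-fold suppressed elsewhere — real exclusive markers are
near-silent outside their type) and a private log2-normal modulation
(sd 1.0) of a random third of background genes, so types separate in PC
space the way real subtypes do. Two regulons (TF + 15 targets each,
8-fold elevated) are active in the GFEM-like and inflammatory types
respectively. Ten mitochondrial genes (`mt-` names) contribute ≈ 2% of
UMIs per cell. Library factors are lognormal (sd 0.25) around ≈ 6,000
UMIs; counts NB with dispersion 0.5. QC violators are planted per rule —
150-gene cells with normal UMI totals, ≈ 700-UMI cells with ≥ 240 genes
detected, 15%-mito cells, 40,000-UMI outliers — so each violator fails
exactly one rule and bookkeeping can be checked cell by cell; the
violation fractions must sum to ≤ 0.5 so a clean majority remains.

**What the generators do not emulate**, and hence what passing tests do
not demonstrate on real data: batch effects, ambient RNA, genuine
doublets (only the UMI-total signature is planted), gene–gene correlation
beyond type programs and regulons, zero-inflation beyond NB sampling,
continuous differentiation trajectories between subtypes, and realistic
transcriptome scale (hundreds of genes, not tens of thousands). Recovery
results on synthetic data bound what the pipeline can do when its model
assumptions hold; they do not certify robustness to real-data artifacts.

## Problem sizes and seeds

The test and acceptance workloads use 700-gene × 15-sample bulk matrices
and 240–360-cell × 400-gene single-cell matrices — sizes chosen so the
planted-recovery statistics are stable while the full suite runs in
minutes on one CPU. Every stochastic routine takes an explicit seed;
child seeds are derived with `numpy.random.SeedSequence`, so no two
stages share a stream. Recovery statistics (gap-statistic k = 7 hits,
ARI ≥ 0.8, screen sensitivity ≥ 95% at noise 0.1, regulon
precision/recall ≥ 0.9) were verified over multiple independent seeds.

## Known limitations

- The DE test has no dispersion shrinkage across genes; with 2–3
  replicates its dispersion estimates are noisy, and the floor at 0.01
  makes the test anti-conservative for genuinely less-dispersed genes.
  For publication-grade bulk DE, import an external table.
- Boundary cells between transcriptionally adjacent subtypes can swap
  clusters across SNN resolutions; the silhouette criterion selects a
  partition, not a guarantee of per-cell correctness.
- The GMM binarization assumes a roughly bimodal AUC distribution; for
  regulons active in a very small cell fraction the lower-component
  fallback threshold is used and precision degrades gracefully rather
  than failing loudly.
- Hypergeometric enrichment treats the background size as a free
  parameter; results shift materially with that choice, which is why it
  is always reported in the output table.
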