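# Methods

## Scope and data model

The package analyzes cell–cell communication in brain single-cell/nucleus
RNA-seq. The in-memory container is an `AnnData` (cells × genes) carrying raw
counts, per-cell condition labels (`sample`, `disease`, `sex`, `region`), a
boolean mitochondrial flag per gene, and — after preprocessing — `cluster`
and `cell_type` columns. A *sub-dataset* is the subset of cells sharing one
observed combination of condition labels; it is the unit on which
communication is scored. Sub-datasets smaller than 50 cells are dropped (a
profile over a handful of cells is meaningless); the threshold is
configurable.

## Preprocessing

1. **QC.** Cells whose mitochondrial count fraction strictly exceeds 20% are
   removed, as are zero-count cells (undefined fraction; logged).
   Mitochondrial genes are identified by an explicit flag supplied with the
   matrix (the simulator names them with the conventional `MT-` prefix).
2. **Normalization.** `x → ln(1 + count / cell_total × 10,000)`. The
   back-transformed per-cell totals equal 10,000 exactly, which the tests
   assert to 10⁻⁶; normalization is invariant to per-cell library-size
   rescaling.
3. **Feature selection.** Standardized variance in the vst style: per gene,
   counts are centred by the observed mean and divided by an expected
   standard deviation taken from a quadratic log₁₀ mean–variance trend fitted
   across genes, clipped at √n_cells; genes are ranked by the variance of the
   clipped standardized counts. The quadratic trend replaces a loess fit; on
   the smooth mean–variance relations of count data the two agree closely and
   the polynomial is dependency-free and deterministic. Ties break
   lexicographically by gene id.
4. **Clustering.** PCA (exact SVD, default 20 components; a fixed count
   replaces any visual elbow choice) on z-scored, ±10-clipped expression;
   a shared-nearest-neighbor graph (k = 15 including self, Jaccard weights,
   pruned below 1/15); Leiden modularity optimization
   (RBConfiguration partition, default resolution 0.8, fixed seed). Labels
   are contiguous integers ordered by decreasing cluster size. Resolution is
   a single configuration value; resolution scanning is out of scope.
5. **Annotation.** Per cluster, candidate markers are genes with two-sided
   Wilcoxon rank-sum p < 0.05 (cluster vs rest) and ln fold change > 0.25
   (fold change on the de-logged means with pseudocount 1). The cluster is
   assigned the cell type with the largest overlap between candidates and the
   type's marker list; ties go to the larger mean fold change over the
   overlapping markers; zero overlap for every type yields "other cells",
   which is excluded from scoring.

## Ligand–receptor resource

Pairs are read from a two-column TSV; `+` joins complex subunits, and the
canonical id is `L1+L2_R1+R2`. Complex expression is the geometric mean of
subunit values, so a zero subunit abolishes the complex — the mass-action
intuition that a receptor missing one chain cannot signal. Cross-species use
goes through a user-supplied two-column ortholog table; pairs with any
unmapped subunit are dropped and counted, and one-to-many rows resolve to the
first mapping in table order. A 51-pair human fixture ships with the package
for tests and examples; real analyses should supply a full database.

## Four scoring schemes and the ISIscore

All four scorers consume the same per-type profile (mean, Tukey trimean
`(Q1 + 2·median + Q3)/4` with linearly interpolated quartiles, detection
fraction, and the global matrix mean μ). Types with fewer than 3 cells are
excluded. For a pair with ligand summary `l` in the sender and receptor
summary `r` in the receiver:

| scheme        | formula                         | summary used | range    |
|---------------|---------------------------------|--------------|----------|
| hill          | `l·r / (0.5 + l·r)`             | trimean      | [0, 1)   |
| regularized   | `√(l·r) / (μ + √(l·r))`         | mean         | [0, 1)   |
| product       | `scaled_l × scaled_r`           | mean, scaled | [0, 100] |
| gated         | `l·r` if both pass the gate     | mean         | absent or > 0 |

For `product`, each gene's per-type means are min–max scaled to [0, 10]
across cell types (constant nonzero → 10, constant zero → 0). For `gated`, a
gene passes in a type iff its detection fraction is ≥ 0.10 *and* its type
mean exceeds its unweighted across-type mean; for complexes every subunit
must pass. Only `gated` produces absences; absence is distinct from a zero
score and is what zero-imputation acts on.

Within one sub-dataset, each method's present entries are min–max normalized
to [0, 1] (all-equal-positive → 1, all-zero → 0; normalization is therefore
invariant to shifting a method's raw scores by a constant). The four
normalized tables are joined on the union of keys with 0 for missing
components, and the ISIscore is their exact arithmetic mean. Min–max rather
than z-scoring is used because the integration requires components on a
common [0, 1] scale; a z-score has neither the range nor the sign structure
the downstream ratio thresholds assume. Keys with ISIscore 0 in every
sub-dataset of a comparison are pruned before testing.

## Differential communication

For each retained key the two condition groups are compared with a two-sided
Wilcoxon rank-sum test. When both groups contain ≥ 3 sub-datasets the samples
are per-sub-dataset ISIscores. With fewer (one dataset per condition) a
rank-sum test on one number per side is impossible, so the test falls back to
per-cell evidence: per sub-dataset, ligand complex expression over sender
cells and receptor complex expression over receiver cells are each resampled
onto a common quantile grid (length = min(n_sender, n_receiver, 200)) and
multiplied elementwise. Quantile matching keeps the sample size bounded and
deterministic where the full outer product of cells would be neither. The
sampling unit used is reported per key.

The exact null distribution is used whenever both groups have ≤ 25
observations (ties enter through average ranks; the exact distribution
carries no tie correction), otherwise the normal approximation with tie and
continuity corrections. A Benjamini–Hochberg column is emitted for reference
but calls use raw p-values: a key is condition-specific iff `p < 0.05` and
`|log₂((mean_A + ε)/(mean_B + ε))| > 3`, both strict, with ε = 10⁻³ guarding
zero means (log base 2; a natural-log reading of the same cutoff would be far
more permissive). Gene panels are formed by flattening all subunits of the
specific pairs, deduplicated and sorted.

## Edge-perturbation subtyping

Within each sample, expression of the edge genes is converted to ascending
average ranks; each single-gene edge scores `rank(ligand) − rank(receptor)`;
complexes are expanded to all subunit-level edges before ranking (ranks are
defined on genes, not complexes). The normal reference is the same edge score
computed on one ranking of the per-gene means over normal samples; the
perturbation matrix subtracts it column-wise. Only ranks enter, so the whole
construction is invariant to any strictly increasing per-sample transform,
and a disease sample ranked identically to the reference yields an all-zero
column — both properties are asserted bit-exactly in the tests.

Disease samples are clustered by consensus clustering: per repetition, 80% of
samples and 80% of edges are subsampled without replacement (seeds derived
from the master seed and the repetition index) and PAM partitions the
Euclidean distance matrix of the subsampled columns for each K in 2..6.
`consensus(i, j)` = co-clustering count / co-sampling count. PAM is k-medoids
with BUILD initialization and best-improvement SWAP descent; because SWAP can
stop in a local optimum, the descent restarts from four additional
deterministic random medoid sets and keeps the lowest-cost solution — on
instances small enough to enumerate, the result matches the exhaustive
medoid-subset optimum, which the tests verify on 50 random instances.

K is selected from the empirical CDF of off-diagonal consensus values:
`A(K)` is the trapezoid area under the CDF on a 101-point grid, `Δ(2) = A(2)`,
`Δ(K) = (A(K) − A(K−1))/A(K−1)`, and the chosen K is the largest K with
`Δ(K)` above a configurable floor (default 0.1) — the last K before the area
gain slows down. The floor is exposed because any "slowed down" rule is a
judgment call; 0.1 cleanly separates the planted-structure regime (Δ ≈ 0.2–0.6
up to the true K) from the noise regime (Δ ≈ 0.03–0.05 beyond it) in the
benchmark studies. Final labels come from PAM on `1 − consensus` at the
chosen K. The default of 1000 repetitions is used for real analyses; the
benchmark studies use 250, which already leaves every co-sampled pair
observed dozens of times at these cohort sizes.

## Disease classifier

Expression of the specific-communication gene panel feeds an XGBoost
classifier (200 trees, depth 3, learning rate 0.1, subsample 0.8,
colsample_bytree 0.5, fixed seed) with a stratified 75/25 split —
stratification avoids degenerate test sets at small n, and the row/column
subsampling decorrelates the trees so the ensemble votes across the panel
rather than latching onto a single split. Performance is the test-set AUC by
the Mann–Whitney rank formulation, which the tests check against trapezoidal
ROC integration. Genes absent from a cohort's platform are dropped and
counted. This module is acknowledged off-the-shelf machinery that closes the
pipeline; its checks are property-based (separable data → AUC 1, label
permutation → chance).

## Synthetic data generator

**Single cell.** Counts are negative binomial with variance
`m + m²/θ`; per-gene baseline means are lognormal with median `nb_mean = 2`
counts/cell and log-sd 0.8, matching the skewed abundance spectrum of UMI
data at a few hundred counts per cell over a 200-gene panel. The dispersion
default θ = 5 corresponds to a biological CV of ≈ 0.45, in the range reported
by count-model fits to real scRNA-seq. Six brain cell types (astrocytes,
endothelial cells, microglia, neurons, OPC, oligodendrocytes) are
distinguished by panels of 8 canonical markers each; markers are simulated as
abundant transcripts (baseline 4 counts/cell — GFAP, MBP or PLP1 are among
the most abundant mRNAs in their types) elevated `marker_fold`-fold in their
own type. Mitochondrial content is controlled by inflating the mito-gene
means of a designated cell fraction to an expected 35% share (5% for the
rest), so the >20% QC filter has a deterministic expected effect.

Planted communication signals follow an *induction-from-repressed-baseline*
design: a planted ligand (receptor) has a depressed baseline mean
(0.2 counts/cell) in its sender (receiver) type and a constitutive baseline
(1.0) in the other types; under the matching condition label the focal-type
mean is multiplied by `signal_fold`. This mimics disease-induced,
cell-type-restricted signaling: in the unaffected condition the focal type
barely expresses the gene (so trimean-based and gated scores vanish and the
across-type scaling puts the focal type at the minimum), while induction
lifts it above the constitutive level. A uniformly expressed gene scaled by a
fold cannot produce condition-restricted communication under concave
log-scale scorers, so this structure is what makes "condition-specific" a
well-defined ground truth. With `signal_fold = 1` the construction is exactly
null between conditions, which the calibration tests rely on.

**Bulk.** Gene log-expression baselines are uniform on [3, 8]; normal samples
add Gaussian noise (sd 0.5). Each of the planted disease subtypes owns a
disjoint set of edges (overlap in genes across subtypes is rejected) and
inverts their ligand-vs-receptor ordering by lowering the ligand and raising
the receptor `rank_shift` log-units (default 4) — an additive shift on the
scale the rank statistic consumes, so the planted signal is exactly the
quantity the subtyping measures.

What the generator deliberately omits: batch effects, doublets, ambient RNA,
spatial structure, realistic gene–gene correlation, and platform-specific
dropout. Passing tests therefore demonstrate that the pipeline recovers the
signals it is designed for under its own noise model, not that it is robust
to every artifact of real cohorts.

## Benchmark study sizes

The canonical studies in `braincomm.studies` (run by `scripts/acceptance.py`
and the end-to-end tests) use: null calibration — 10 vs 10 sub-datasets,
80 cells/type, 15 pairs (540 tested keys); planted recovery — 10 planted +
20 background pairs, fold 8, 5 vs 5 sub-datasets, 40 cells/type; subtype
recovery — 20 normal + 80 disease samples, 4 subtypes × 10 edges among 60
pairs, 250 consensus repetitions; prediction — 60 normal vs 100 disease
samples, 40-gene panel, 20 permutation seeds; annotation — 60 cells/type at
marker fold 4. These sizes give stable statistics (binomial 99% bands on the
calibration fraction, ARI at saturation for the planted structures) while
each study completes in seconds on one CPU.

## Known limitations

- The four scorers are single representative formulas per tool family, not
  re-implementations of the published tools; raw scores are not comparable to
  any specific tool's output, only the integration logic is.
- Min–max normalization ties every ISIscore to the score range observed in
  its own sub-dataset; comparisons across sub-datasets are on relative rank,
  and a sub-dataset with one extreme outlier pair compresses the rest.
- The per-cell fallback test treats cells as exchangeable replicates, which
  understates between-sample variability; it exists to make two-sub-dataset
  comparisons possible at all and its p-values should be read accordingly.
- The delta-area floor, SNN parameters, and clustering resolution are
  heuristics exposed as configuration; no claim of optimality is made.
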