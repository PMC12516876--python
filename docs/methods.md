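# Methods

## Cross-modal model

The package joins two measurements of the same tissue type: an smFISH
spatial assay counting transcripts of a small probe panel per segmented
cell, and whole-transcriptome scRNA-seq. The working assumption is that a
cell's expression over the shared panel identifies its transcriptional
state well enough that its nearest scRNA-seq neighbors (cosine similarity
on CPM) are cells of the same state. Two consequences are exploited:

- **Imputation** transfers the neighbors' whole-transcriptome profiles to
  the spatial cell as a similarity-weighted average with weights
  normalized to sum to one. The estimate is a convex combination, so every
  imputed value lies within the min/max of the neighbor values; cells
  whose qualifying similarities sum to zero are reported missing rather
  than filled with zeros.
- **Label projection** runs the same search in reverse (scRNA-seq cells
  querying spatial cells) and transfers the majority cluster label among
  the k neighbors. Neighbors with similarity ≤ `min_similarity` (default
  0.3) are discarded first; a cell whose remaining labels are all unique
  gets no projection. Frequency ties are broken toward the label with the
  larger summed similarity; an exact tie also yields no projection, so
  the procedure is deterministic.

Cosine similarity is computed exactly (chunked dense products, no
approximate index): the data sizes here — tens of thousands of cells by
~100 panel genes — do not justify approximation, and exactness makes the
search testable against a brute-force oracle. Similarity ties are broken
by reference cell id in lexicographic order.

Stages are integrated separately and merged afterward; a gene imputed for
only one stage is *missing* (NaN) for the other stage's cells, never zero,
and the merged gene count obeys inclusion–exclusion.

## Normalization conventions

- **CPM** (`raw / cell_total × 10⁶`) is the layer used for cross-modal
  similarity and imputation — the one normalization both modalities admit
  without a transcriptome-wide size model. The log-transformed alternative
  is exposed (`layer="lognorm"`) for sensitivity checks.
- **LogNormalize** (`ln(1 + raw / total × scale_factor)`) is the layer for
  marker statistics and cluster profiles, matching the convention of the
  standard single-cell toolchain.
- QC keeps cells inside *closed* intervals of detected genes
  ([1500, 25000] by default) and total UMIs ([8000, 300000]); the interval
  reading of "A to B" is inclusive.
- Homeolog aggregation sums member columns per triad; members absent from
  a matrix contribute zero rather than erroring, because cross-study
  panels rarely cover all three subgenome copies. Sums commute with
  cluster averaging, so aggregation may be applied to profiles directly.

## Cluster correlation

Informative genes satisfy CV > 0.5 across cluster means and cluster-sum
within [0.1, 20]. CV uses the sample standard deviation (ddof = 1;
configurable), appropriate for the small n that cluster counts represent;
genes with zero mean are excluded because their CV is undefined. The sum
band is closed: only strictly-outside genes are eliminated. The filter is
idempotent. Correlations are plain Pearson over the gene vector of each
cluster; zero-variance clusters get missing correlations and are reported.
Hierarchical ordering of correlation matrices (Euclidean distance,
complete linkage) is provided for display only.

## Markers, screens, diagnostics

The marker test is a two-sided Wilcoxon rank-sum (one cluster vs all other
cells) under the normal approximation with tie and continuity correction.
pct.1/pct.2 are the fractions of cells with any expression inside/outside
the cluster. log2FC de-logs the group means and adds the pseudocount of 1
at the *group* level: `log2((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))`.
Adjustment is Bonferroni over all (gene, cluster) tests by default, with
Benjamini–Hochberg available. Clusters smaller than 3 cells get records
with missing p. Both filter presets apply strict inequalities exactly as
their thresholds read.

The co-expression screen correlates a target with every other *detected*
gene (expressed in ≥ 3 cells, mirroring the clustering QC) across all
cells and selects r > mean + 4·SD of the screen's r distribution. The
target itself and constant genes are excluded from the mean/SD —
including the target's own r = 1 would inflate the SD. The selection
threshold is a property of the screen's null distribution: in a
homogeneous cell population it sits near 0.1 and the planted partner of a
0.7-latent-correlation pair clears it by a wide margin, while strong
cluster structure widens the null (cluster-correlated gene pairs are
genuine co-expression, not error).

Protoplasting diagnostics score each cluster's markers by overlap with a
known stress-gene list and by absence from intact-tissue bulk RNA-seq;
agreement of the two percentage vectors across clusters is summarized by
their Pearson correlation.

## Spatial statistics

Spot densities are counts per 100 μm² inside a polygon region, with
boundary-inclusive membership (even-odd rule; a spot on a vertex counts).
Coordinates are μm in image convention (y downward). Stage comparisons
average technical replicates (sections of the same spike) into one value
per biological replicate, then use a two-sided Welch t-test — a robust
default for the tiny, possibly heteroscedastic group sizes involved
(e.g. 4 vs 2 spikes). A zero-denominator fold change is reported as
infinite with a flag, never raised.

Region assignment runs Tukey HSD across the bulk regions per gene; the
max-mean region wins when it beats the *runner-up* at α (beating all
regions is available via `require_all`). Zero within-group variance with
unequal means is a degenerate one-way layout: the winner is assigned with
p reported as 0 and flagged. Region enrichment is a chi-square
goodness-of-fit of marker winning-regions against uniform, df = regions−1,
with a small-count flag below 5 assigned genes.

## Synthetic data

The generator emulates the statistical structure the method relies on,
not tissue realism:

- One **shared mean profile** (clusters × genes): lognormal per-gene
  baselines times cluster-specific lognormal fold changes (log-sd 1.0).
  Both modalities draw from it — the spatial modality restricted to the
  panel — scaled so expected library sizes hit the configured means
  (defaults 300 spatial counts over the panel, 5,000 scRNA counts over
  2,000 genes, echoing the sparse-panel vs transcriptome asymmetry).
- **Counts** are negative binomial parameterized by mean μ and dispersion
  α with variance μ + αμ² (gamma–Poisson mixture; α = 0 is exactly
  Poisson). Default α = 0.3, a moderate single-cell overdispersion.
  Per-cell library factors are lognormal with mean one (log-sd 0.3), so
  expected counts stay equal to the planted means.
- **Spatial layout**: each cluster owns one rectangular tile of the grid
  and its cells are jittered uniformly within the tile — contiguity is
  what integration tests need; no cell-overlap guarantees are attempted,
  and spot-in-polygon tests use disjoint fixtures.
- **Planted co-expression**: the two genes of a pair are co-regulated —
  they share one cluster fold profile and a moderate baseline (5 relative
  units) — and additionally share a per-cell lognormal latent factor,
  mixed per gene as √ρ·z + √(1−ρ)·ε with unit log-sd and mean-one
  correction. Cluster co-membership and the latent factor are both real
  drivers of observed co-expression; at ρ = 0.7 and 3,000 cells the
  realized log1p-count Pearson is ≈ 0.6 (Monte-Carlo), well clear of the
  0.3 bound the tests assert.
- **Planted stress genes** are induced by a multiplier only in designated
  clusters of the scRNA-seq modality (protoplasting does not affect the
  fixed tissue). An optional baseline override lets them be near-silent in
  intact tissue, the profile real protoplasting-response genes show.
- **Spot tables** explode each (cell, gene) count into exactly that many
  uniform points within the cell's disc, conserving counts per gene and
  per cell. **Region tables** are base expression × region multiplier ×
  lognormal noise, with ≥ 2 replicates enforced.

What passing tests on this generator do *not* show: robustness to
segmentation errors, probe efficiency differences between genes, batch
effects between replicates, doublets, or continuous (non-cluster)
expression gradients — none of which the generator emulates.

## Problem sizes and numerical choices

The default synthetic study conditions are 6 clusters, 1,500 spatial ×
3,000 single cells, a 95-gene panel inside 2,000 genes — large enough for
the recovery statistics to be stable (imputation median per-gene r ≈ 0.997,
projection accuracy ≈ 0.999 at seed 1) while the full pipeline runs in
well under a minute. Calibration checks use dedicated conditions: the
co-expression screen's null calibration uses a homogeneous population (one
planted pair among 500 null genes, 3,000 cells); chi-square calibration
uses 2,000 uniform multinomial triplets of 30 genes.

Numerical conventions worth noting: cosine similarities are clipped to
[0, 1] against floating-point drift; similarity ties break by reference
id, majority ties by summed similarity then no-projection; CPM rows are
exact to 1e-9 relative; MTX round-trips are bit-exact for integer layers
and within 1e-12 relative for real layers (written at 17 significant
digits); all randomness flows through `numpy.random.default_rng` seeded
from a single configuration field.

## Known limitations

- Cluster labels are inputs everywhere; the package does not cluster.
- The imputation transfers no uncertainty: a weighted average of 5
  neighbors underestimates expression variance and cannot extrapolate
  outside the reference's repertoire.
- The contribution-matrix fractions are counts over smFISH cluster size;
  when the projected (scRNA-seq) population outnumbers a spatial cluster,
  fractions can exceed 1 — they are enrichment weights, not proportions
  of a common total.
- Bulk region tables must arrive pre-normalized (TMM or similar); no
  size-factor estimation is performed here.
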