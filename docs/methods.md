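# Methods

This note documents the models and procedures implemented in
`chromclust`, the defaults and why they were chosen, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Input model and counting

The unit of input is a barcode-resolved read record: a cell barcode, a
chromosome, the 5′ position of read 1, and optionally the 5′ position of
read 2. Public single-cell BED files are treated as single-end records
(read start = read-1 position). All coordinates are 0-based, half-open.

Duplicate removal reflects the artifact structure of droplet single-cell
chromatin protocols and is applied per barcode in a fixed order:

1. **PCR duplicates** — records identical in (chrom, pos₁, pos₂)
   collapse to one;
2. **RT duplicates** — surviving records identical in (chrom, pos₁)
   collapse to one (linear amplification re-copies a fragment with a
   different second read);
3. **window duplicates** — surviving records whose pos₁ falls in the
   same genome-anchored, non-overlapping 50 bp tile [k·w, (k+1)·w)
   collapse to one, as reads likely originating from the same
   nucleosome.

Single-end records skip rule 1. Within a duplicate group the survivor is
the record with the smallest (pos₁, pos₂, input index), which makes the
output multiset independent of input order; the tie-break on input index
only distinguishes exactly identical records. Deduplication is
idempotent. For pre-processed public BED inputs deduplication is
optional (`deduplicate` config flag), since such files are usually
already duplicate-collapsed.

Counting assigns each read to features by the single point pos₁, so in
bins mode every retained read inside the tiled genome is counted exactly
once (Σc = retained reads, asserted by tests). TSS windows may overlap;
a read then increments every containing window, so per-cell totals in
TSS mode can exceed the read count — a documented consequence of the
window model. Feature modes:

- **bins**: width *w* tiles (default 50 000 bp; broad repressive marks),
  final partial bin kept, covering every base exactly once;
- **peaks**: user-provided BED intervals (e.g. external peak-caller
  output, optionally stitched with `merge_close_intervals`, default
  merge distance 5 000 bp);
- **tss**: ±flank windows around TSSs (default 2 500 bp; sharp active
  marks), clipped at position 0 and chromosome ends.

Sample labels come from an explicit manifest TSV (cell_id → sample),
never from file-name heuristics.

## Quality control

Defaults: minimum 1 600 unique reads per cell; removal of the
⌈q/100 · n⌉ highest-coverage cells at q = 5% (doublet suspects), ties
broken by cell index; features kept when detected (count ≥ 1) in at
least 1% of the cells whose total exceeds 1 000 reads. Cells are
filtered first; the feature-support set is computed from raw totals of
the retained cells. An optional exclusion BED drops any feature
overlapping a listed interval by ≥ 1 bp (e.g. copy-number-variable
segments).

One subtlety: the top-percentile rule removes a *count* of cells that
depends on how many survive the minimum-reads rule, so the composed
filter is not jointly monotone in the minimum-reads threshold — raising
the threshold can, rarely, readmit a high-coverage cell because fewer
cells are trimmed from the top. The minimum-reads rule alone is monotone
and is tested as such.

Normalization is the RPKM convention,
x = c / (T/10⁶) / (L/10³). Only the two normalizing quantities (cell
total, feature length) matter downstream; the constants set a global
scale and are fixed so the log2 fold-change pseudocount (below) is
interpretable.

## Reduction and the correlation filter

PCA is computed by SVD of the feature-centered cells × features matrix
(no unit-variance scaling), keeping 50 components by default, silently
reduced to the matrix rank with a warning. The sign of each component is
fixed so its largest-magnitude loading is positive, making scores
reproducible. All cell–cell correlations downstream (filter and
clustering) are Pearson correlations of the PC score rows, not of raw
features.

Isolated cells destabilize clustering. The filter threshold *t* is the
nearest-rank 99th percentile (default) of the upper-triangle pairwise
correlations of a *randomized* dataset: each feature row of the
normalized matrix independently permuted across cells, which preserves
per-feature marginals while destroying cell structure. This null choice
(permutation of the normalized matrix, correlations measured on its PCA
scores) is this package's documented convention; alternatives (permuting
raw counts, correlating raw features) would shift *t* but not the
mechanism. A cell is kept iff it correlates at ≥ *t* with at least p%
(default 1%) of the other cells.

## Consensus clustering

The base clusterer is agglomerative with distance d = 1 − Pearson(r) on
PC scores and Ward linkage; cutting the tree at *k* gives a partition
(labels renumbered in order of first appearance for determinism). For
each *k* in 2..k_max (default 10), `n_iter` (default 1000) iterations
each sample ⌈frac·n⌉ cells (frac default 0.8) without replacement and
re-cluster; the consensus matrix entry m_ij is the fraction of
iterations in which i and j co-clustered among those where both were
sampled. Pairs never co-sampled get m_ij = 0 with a warning — at
n_iter ≥ 100 this is vanishingly rare. Per-iteration RNG streams are
spawned deterministically from one master seed.

Stability statistics: the empirical CDF of upper-triangle consensus
values gives A(k) = Σ (x_{i+1} − x_i)·CDF(x_i) over sorted unique
values; Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2, with
Δ reported as NaN when A(k−1) = 0. A plateau in Δ(k) marks the knee at
which extra clusters stop adding stable structure; the choice of *k* is
deliberately left to the user (`chosen_k`) — the Δ table is advisory.
Item consensus (a cell's mean consensus with its cluster's other
members; 1 by convention for singletons) flags unstably assigned cells.
The final partition at the chosen *k* clusters the consensus matrix
itself (distance 1 − m, Ward), the standard consensus-clustering
practice, rather than any single data clustering.

## Differential enrichment

Per cluster (one-vs-rest, or one-vs-chosen-cluster), each feature's
normalized values are compared with a two-sided Wilcoxon rank-sum test:
exact null enumeration when the pooled size is ≤ 30 and tie-free,
otherwise the normal approximation with tie and continuity correction.
P-values are BH-adjusted across features *within* each cluster's
comparison (not pooled across clusters), matching the per-cluster
region counts users expect to read off. Fold change is
log2((mean_A + 1)/(mean_B + 1)) on normalized values; the pseudocount
of 1 on the RPKM scale bounds fold changes when a group mean is zero.
Calls: enriched iff q < 0.01 and log2FC > 1; depleted iff q < 0.01 and
log2FC < −1 (defaults). Features with zero signal in both groups are
skipped (p undefined) and reported as such; clusters with < 2 cells are
skipped with a warning. Batch-blocked testing and negative-binomial
(raw-count) testing are out of scope; the `--batch-correct` hook exists
but errors.

## Annotation and gene-set enrichment

A gene is associated with a region when its TSS lies in
[start − d, end + d) with d = 1 000 bp by default, strand ignored.
The enrichment universe is the set of genes associated with *any*
feature surviving QC — restricting the null to assayable genes rather
than the whole annotation. Per gene set (GMT input; symbols matched
case-insensitively; annotation restricted to protein-coding, antisense
and lncRNA biotypes): K = |set ∩ universe|, k = |set ∩ query|,
p = P(X ≥ k) hypergeometric, BH across all sets tested; enriched and
depleted region lists are tested separately. Genes hit by multiple
regions count once.

## Evaluation metrics

Adjusted Rand index (contingency-table definition, checked against an
independent formula oracle); assignment scores (fraction of a sample's
cells per cluster, rows summing to 1); Pearson chi-squared
goodness-of-fit per cluster against overall sample fractions, df = S−1,
no continuity correction; two-sided Fisher exact test with the
probability-mass two-sided rule (all tables with the same margins at
most as probable as the observed one).

## Synthetic data generator

The generator emulates multi-sample mixtures of populations that differ
in *which* bins carry signal: population π has a set of signal bins
where read density is enrichment_ratio × background. Per-cell totals
are log-normal (defaults: ln-mean 8 ≈ 3 000 reads median, ln-sd 0.4),
chosen so the default 1 600-read QC threshold bisects a realistic
coverage range. The read-level generator places each read's bin
multinomially and its position uniformly within the bin; the matrix
shortcut draws negative-binomial counts (shape 2.0 by default — the
overdispersion typical of single-cell counts) around the same per-bin
means. The planted benchmark (four populations × 100 cells, 2 000 bins,
100 disjoint signal bins each at ratio 20, two sample labels assigned
round-robin) adds one gene per bin midpoint, a 20-gene planted set per
population sampled from its signal bins, and decoy sets sampled
uniformly.

What the generator does **not** emulate: batch effects, fragment-length
or GC biases, mappability structure, chromatin-domain autocorrelation
along the genome, doublets as mixtures (high coverage stands in), or
copy-number variation. Passing the planted benchmark therefore shows the
machinery recovers designed structure at realistic sparsity and
coverage heterogeneity; it does not certify performance on real data
with confounders outside this model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at
4 × 100 cells × 2 000 bins with 200 consensus iterations — a scale
chosen as the package's reference configuration for fast, deterministic
verification; the library itself has no such limits (the pipeline is
sparse end-to-end until PCA densifies the QC-filtered matrix). Other
conventions: nearest-rank percentile for the correlation threshold;
Ward linkage on the averaged, diagonal-zeroed distance matrix with tiny
negative correlations clipped at 0; constant PC score rows raise an
error naming the cell (Pearson undefined); BH within comparison
families as stated above; all RNG via `numpy.random.default_rng` with
explicitly passed seeds, spawned per consensus iteration.

## Known limitations

- No internal peak caller: peaks mode consumes external BED/narrowPeak.
- No batch correction (reserved hook), no blocked differential testing,
  no negative-binomial count model.
- No automatic choice of k; Δ(k) is advisory by design.
- 2-D visual embeddings (t-SNE/UMAP) are not part of the computational
  contract and are not produced.
- Gene-symbol matching is exact (case-insensitive); no alias resolution.
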