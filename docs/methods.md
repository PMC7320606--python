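# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they are what they are, what the synthetic-data generator
does and does not emulate, and the numerical choices that make runs
bit-reproducible.

## Input handling and normalization

Expression matrices are accepted as 10x-style MatrixMarket directories
(`matrix.mtx` + `features.tsv` + `barcodes.tsv`, gzipped or plain), dense
tab-delimited text (genes × cells) or 10x HDF5. A matrix whose entries are
all integers is flagged as raw counts; anything else is treated as
unknown-normalized. Duplicate gene symbols are disambiguated
deterministically by suffixing `.1`, `.2`, … so no rows are silently lost.

Counts are normalized to CPTT — counts per ten thousand — followed by a
log2(1+x) transform: `value' = log2(1 + 10000·value/cell_total)`. The
1-pseudocount convention keeps zeros at zero and makes the transform
invertible (`2^v − 1`), which the normalization-identity tests rely on.
Cells with zero total counts are dropped with a warning rather than
aborting the run, because filtered droplet matrices can contain empty
barcodes. Normalization is idempotent: a second call is a warned no-op.

Gene-class exclusions (mitochondrial, L/S ribosomal, immunoglobulin) are
decided by symbol prefix (`MT-`/`mt-`, `RPL/RPS/Rpl/Rps`, `IGH/IGK/IGL`) —
the only annotation-free rule — and can be overridden or extended with
explicit lists. The protein-coding filter requires a user-supplied symbol
list; without one it is skipped with a warning rather than guessed.

## Stage 1 — downsampling

* Dispersion (variance/mean) is a count-scale statistic, so it is computed
  on raw counts when available and on de-logged CPTT values otherwise.
  Sample variance uses the n−1 denominator.
* kNN search is exact (brute-force in float32) at the scales this package
  targets; the neighbour contract (directed edges to the min(k, n−1)
  nearest cells, self excluded) is independent of the backend.
* PageRank uses damping 0.85 — the canonical value — with a total-residual
  tolerance of 1e-8 (the networkx per-node tolerance is divided by n) and
  at most 200 iterations; scores sum to 1. Ties in the top-2500 selection
  break by cell id so runs are reproducible.
* Louvain "resolution 0" is read as the most granular cut of the Louvain
  dendrogram: the first level of `networkx.community.louvain_partitions`
  at resolution 1, i.e. the smallest communities before any aggregation
  pass merges them. Positive resolutions run standard modularity Louvain.
  Community ids are renumbered by their smallest member so labels are
  stable.
* Community quotas use ⌊s/n⌋ (never rounding up), which guarantees
  Σ m_i ≤ s. The single most-representative-cell definition (smallest
  summed Euclidean distance to co-members) generalizes to m_i picks by
  taking the m_i smallest distance sums, ties broken by cell index.
* After Louvain reduction the kNN graph is rebuilt on the representatives
  rather than sub-induced from the full graph; a sub-induced graph would
  leave representatives with truncated neighbourhoods.

## Stage 2 — feature selection

The fold filter retains a gene when its 3rd-highest log2 value exceeds
max(0, 3rd-lowest) by log2(4) — that is, at least 3 cells sit 4-fold above
a pseudocounted baseline — and the gene is not constant. Requiring 3 cells
makes the filter robust to single outlier cells; both numbers are
configuration fields.

Correlated-module discovery computes all-pairs Pearson ρ among the
variable genes, keeps genes with ≥ 4 partners at ρ ≥ threshold, and raises
the threshold by 0.1 (starting from 0.2) while more than 5 000 genes
survive, erroring past 0.9. The partner minimum of 4 is a reimplementation
choice surfaced in `CorrelationConfig.min_partners`.

The hybrid clusterer is a simplified, fully deterministic HOPACH: at each
node it evaluates 2–9 medoid children, scores each candidate partition by
median split silhouette (the median, over children, of the median member
silhouette under the child's own best 2-way split — low means the children
resist further splitting), accepts the split only when the partition's
median silhouette clears a separation floor, orders children by medoid
proximity, and collapses adjacent siblings whose pairwise silhouette falls
below the floor. The floor is max(0.15, 1.5/√n): silhouettes of arbitrary
splits inflate roughly as 1/√n at small node sizes, and the raised floor
prevents fragmenting small homogeneous nodes. Medoid search is exact
(exhaustive over subsets) up to 30 000 candidate subsets and otherwise
uses farthest-point seeding from the global medoid plus Voronoi
iteration — every tie breaks by index. Recursion depth is capped at 3.
Fidelity to the R HOPACH implementation's cluster numbering is explicitly
not promised.

Guides are module medoids by mean intra-module correlation; cell-cycle
genes are never chosen as guides, and when cell-cycle exclusion is on, a
module whose medoid is a cell-cycle gene is dropped outright (its
coherence is taken to be cell-cycle-driven). Transcription-factor biasing
is available behind a user-supplied TF list and is off by default. Three
rounds of module discovery → guide selection → guide-correlation expansion
are run (the third round's supervised expansion is the "Guide3" matrix);
the variance filter is applied once, before round 1. Cells of the Guide3
matrix are ordered by cosine hybrid clustering (Euclidean and correlation
metrics are selectable).

## Stage 3 — rank estimation and factorization

The Guide3 matrix is z-scored per gene (zero-variance genes dropped with a
warning); the choice of per-gene rather than per-cell standardization
matches the (g−1, c) degrees of freedom in the Tracy–Widom centering. The
eigenvalues of the c × c Gram matrix ZᵀZ are compared against the
largest-eigenvalue null for a white Wishart matrix:
μ = (√(g−1)+√c)², σ = (√(g−1)+√c)(1/√(g−1)+1/√c)^⅓, and an eigenvalue is
significant when (λ−μ)/σ exceeds the TW1 quantile at P < 0.001. The TW1
quantile is evaluated with the shifted-gamma approximation of Chiani
(2014); its 5 %/1 %/0.1 % points (0.9793/2.0234/3.2724) are asserted in
the tests. All eigenvalues are tested against the same largest-eigenvalue
null. The SNMF rank is r = 2k, floored at 2 (a rank below 2 cannot
partition) and capped at min(g, c); the user can force any rank.

Factorization is coordinate-descent NMF on the cells × genes matrix with
an optional L1 penalty on H (default weight 0, surfaced in config).
Initialization is plain NNDSVD — each SVD pair split into positive and
negative parts, the dominant part kept — implemented in-package so that
the initial objective is observable; the fitted objective is asserted
never to exceed it. NNDSVD plus a fixed coordinate order makes repeated
runs bit-identical. Provisional labels are argmax over each cell's W row,
ties to the lowest factor index; a cell with an all-zero W row is assigned
to the factor with the largest H norm and flagged.

## Stage 4 — marker fitness

MarkerFinder correlates every non-constant gene against each cluster's 0/1
indicator profile and assigns it to its best cluster (ties to the lower
cluster id). A cluster is fit when ≥ 2 of its genes reach the fitness ρ
(defaulting to the auto-tuned ρ from feature selection); fit clusters keep
their top 60 markers with ρ strictly > 0.3, boundary ties broken by gene
id. A factor that attracted cells but no genes at all is dropped with its
own reason rather than silently ignored. After any drop, markers are
recomputed on the cells of the surviving clusters only — a dropped
cluster's cells no longer dilute the references — iterating until the fit
set is stable. Dropping a cluster never removes cells from the dataset;
its cells are reassigned by the stage-5 classifier.

A note on doublet-style clusters: a population whose profile is an exactly
linear mixture of two parents adds no reconstruction benefit to NMF, so
its cells are absorbed into the parent factors under argmax-of-W while the
surplus factors left by the 2k rank slack attract no unique markers and
are dissolved by the fitness filter. The observable guarantee is therefore
that no marker-less cluster survives to the final output and every cell
ends up in a marker-supported cluster — not that the doublet population is
captured by one specific factor.

## Stage 5 — classification

The feature space is the union of the fit clusters' marker genes (at most
60 per cluster); marker genes missing from a matrix are imputed as zero
with a warning. Centroids (arithmetic means per cluster) are exported for
diagnostics, but the SVM trains on the downsampled cells themselves —
training on centroids would give two-instances-per-class problems no
margin to work with. Cells of dropped clusters are excluded from training.
The classifier is scikit-learn's LinearSVC (linear kernel, one-vs-rest,
C = 1, fixed random_state) and its decision values are reported per cell.
A single surviving class degenerates to a constant labeling with a
warning.

## Evaluation metrics

* ARI: standard pair-counting adjusted Rand index (verified against a
  brute-force pair-counting oracle to 1e-12 in the tests).
* Specificity: s_ij = 100·|i∩j|/|i| on the percent scale; the aggregate
  ARI merges every test cluster whose specificity for some reference
  population is strictly above 75 (max specificity wins; ties go to the
  lower reference id) before scoring. Merging is test-side only.
* Donor enrichment: one-sided hypergeometric (Fisher-exact) tail
  probabilities mapped through the standard-normal inverse, positive for
  over-representation, capped at |z| = 38 where the tail underflows.
* Retention: per-population counts of cells surviving a selection with a
  ≥ 5-cell detection flag, plus an SRS baseline with both empirical draws
  and the analytic hypergeometric probability.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
negative-binomial counts (var = μ + φμ², φ = 0.5 by default) around
lognormally spread gene baselines (mean 0.5 counts/gene/cell, a typical
droplet depth at ~2000 genes), disjoint marker programs uplifted
`marker_fold`-fold per cluster, exact largest-remainder apportionment of
cells to populations (so a 0.1 % population of 20 000 cells has exactly 20
cells), optional doublet-style clusters (50/50 parent mean mixtures with
no unique genes, 5 % of cells each — an empirically typical droplet
doublet rate), and optional multiplicative donor effects on a random 10 %
gene subset. Everything derives from one seed.

It does **not** emulate ambient RNA, UMI saturation, splicing, gene–gene
correlation within a population beyond the shared program, or
library-size variation between cell types. Passing tests therefore
demonstrate that the algorithms behave as specified on data satisfying
their own assumptions; they do not certify performance on real tissues.

Fixture sizes used by the tests and the reproduction script are the
package's own choices: 3 000 cells × 2 000 genes for the four-population
recovery and doublet runs, 20 000 cells × 1 000 genes (eight populations,
one at 1 %) for the downsampling retention study, 1 200 cells for the
determinism check.

## Determinism

Every stochastic step is either seeded (Louvain, fixture generation, SVM)
or algorithmically deterministic (NNDSVD initialization, exhaustive or
farthest-point medoid search, explicit tie rules on cells, genes, factors
and clusters). Two runs with the same seed and input produce bit-identical
output files; this is asserted end-to-end in the tests.

## Known limitations

* The hybrid clusterer is a behavioural, not numerical, reimplementation
  of HOPACH; cluster numbering and fine ordering differ from the R
  package.
* Rank estimation assumes the z-scored Guide3 matrix is approximately
  white under the null; heavily structured residuals can inflate k.
* The fitness filter inherits the auto-tuned ρ; on very sparse data where
  the threshold has risen far above 0.2, legitimate small clusters can be
  dropped — the rank override exists for that case.
* Exact kNN is O(n²) in the cell count; the Louvain pre-reduction keeps
  this tractable to a few hundred thousand cells but the package does not
  target millions of cells without raising the downsample cutoff.
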