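# icgs2 — iterative clustering and guide-gene selection for scRNA-seq

`icgs2` detects discrete **and rare** cell populations in single-cell
RNA-seq expression matrices without asking the user to choose the number of
clusters, a correlation cutoff or a sampling depth. It is aimed at analysts
working with droplet datasets from a few hundred to a few hundred thousand
cells who want reproducible, marker-supported cell clusters rather than a
partition of an embedding.

## The method

The workflow has five stages, each with automated parameter estimation:

1. **PageRank downsampling.** For datasets above 2 500 cells, a directed
   k-nearest-neighbour graph (k = 10, Euclidean distance over the top 500
   dispersion genes, dispersion = var/mean) is built over the cells and the
   2 500 cells with the highest PageRank scores (damping 0.85) are kept.
   Because each cell links only to its 10 nearest neighbours, rare
   populations form tight mutually linked neighbourhoods and survive the
   sampling. Above 15 000 cells, Louvain community detection first reduces
   the graph: community *i* contributes
   *m_i* = min(*c_i*, ⌊*s*/*n*⌋) of its most central members (smallest
   summed intra-community Euclidean distance), with *s* = 10 000 = 4 × the
   downsample cutoff, before PageRank runs on a graph rebuilt over the
   representatives.
2. **Correlation feature selection.** Counts are CPTT-normalized
   (counts-per-ten-thousand, log2(1+x)); genes spanning ≥ 4-fold in ≥ 3
   cells enter an all-pairs Pearson correlation. Genes with ≥ 4 partners at
   ρ ≥ 0.2 are retained; if more than 5 000 survive, the cutoff rises by
   0.1 and the step repeats. Retained genes are grouped into modules by
   hybrid (HOPACH-style) medoid clustering, each module contributes a
   guide gene (its correlation medoid; cell-cycle-driven modules can be
   excluded), and a supervised correlation against the guides over three
   rounds yields the final feature matrix ("Guide3") with cells ordered by
   cosine hybrid clustering.
3. **Sparse NMF with automated rank.** The Guide3 matrix is per-gene
   z-scored and the eigenvalues λ of its cell–cell Gram matrix are tested
   against the Tracy–Widom largest-eigenvalue null with location
   μ = (√(g−1)+√c)² and scale σ = (√(g−1)+√c)(1/√(g−1)+1/√c)^⅓. The rank is
   r = max(2, 2k) where k is the number of eigenvalues with P < 0.001.
   NNDSVD-initialized sparse NMF (deterministic) factorizes cells × genes
   into W·H; each cell's provisional cluster is argmax of its W row.
4. **Cluster fitness.** MarkerFinder correlates every gene with each
   cluster's idealized 0/1 reference profile and assigns it to its
   best-correlated cluster. Clusters with fewer than 2 genes above the
   auto-tuned ρ are dissolved (this removes doublet-style clusters that
   have no uniquely expressed genes); surviving clusters keep their top 60
   markers with ρ > 0.3.
5. **SVM assignment of all cells.** A linear-kernel SVM (one-vs-rest,
   C = 1) trained on the downsampled cells of fit clusters in marker-gene
   space assigns **every** cell of the original dataset, including those
   removed by downsampling.

Evaluation utilities implement the adjusted Rand index (ARI), per-cluster
specificity s_ij = 100·|i∩j|/|i|, an aggregate ARI that merges test
clusters > 75 % specific to one reference population before scoring,
donor-enrichment z-scores (one-sided Fisher-exact/hypergeometric), and
retention reports comparing intelligent downsampling with simple random
sampling (SRS).

A synthetic-data module generates negative-binomial count matrices with
planted marker programs, rare populations (down to 0.1 %), doublet-style
mixture clusters and donor batch effects, so the whole pipeline can be
exercised without external downloads.

## Worked example

Simulate a 1 000-cell dataset with four planted populations, cluster it and
score the result against the planted truth:

```bash
icgs2 simulate --n-cells 1000 --n-genes 1500 --clusters 4 \
    --markers-per-cluster 50 --seed 7 --outdir demo_sim
icgs2 run --input demo_sim/counts.tsv --format tsv --seed 7 --outdir demo_out
```

which prints:

```
INFO read 1500 genes x 1000 cells from demo_sim/counts.tsv
INFO 1500 genes retained after class filters
INFO downsampled 1000 -> 1000 cells
INFO feature selection: 200 genes, 1000 cells, final rho 0.20
INFO rank estimation: 3 significant eigenvalues -> rank 6
INFO cluster 1 dropped: only 0 marker(s) at rho >= 0.2 (need 2)
INFO 4 fit clusters
rho_final=0.20 rank=6 fit_clusters=4 cells=1000
```

Reading: 1 000 cells is below the 2 500-cell cutoff, so no downsampling
occurs. Feature selection keeps 200 correlated genes at the starting
ρ = 0.2 (no auto-increment was needed). Three eigenvalues beat the
Tracy–Widom bound, so SNMF runs at rank 6; two surplus factors attract no
unique markers — one is dissolved by the fitness filter, one receives no
cells — leaving exactly the four planted populations. Scoring the final
labels against the planted truth:

```bash
icgs2 evaluate --test test_labels.tsv --ref ref_labels.tsv
# ARI=1.0000 aggregate_ARI=1.0000
```

`demo_out/` also contains the marker-gene table, the Guide3 matrix, the
rank-estimation report, per-cell SVM decision scores and the downsampled
cell list as plain TSV/text files.

The same pipeline is available as a library (`icgs2.run_pipeline`,
`icgs2.generate_dataset`, `icgs2.adjusted_rand_index`, ...), which is how
the test-suite and the reproduction script drive it.

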