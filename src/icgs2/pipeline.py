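"""End-to-end orchestration of the five-step clustering workflow.

read -> CPTT normalize -> gene-class filter -> [optional outlier-cell
filter] -> PageRank downsampling -> correlation feature selection ->
Tracy-Widom rank estimation -> sparse NMF -> provisional assignment ->
MarkerFinder / cluster fitness -> centroids + linear SVM -> final
assignment of every cell. Every automatically chosen parameter (final rho,
rank, dropped clusters) is logged, and all text artifacts are written to
the output directory.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .classifier import Centroids, TrainedClassifier, assign_all_cells, compute_centroids, train_classifier
from .core_io import (
    ExpressionMatrix,
    GeneFilterConfig,
    NormState,
    apply_gene_filters,
    normalize_cptt,
    read_matrix,
)
from .downsample import DownsampleConfig, downsample_cells
from .feature_selection import CorrelationConfig, Guide3Matrix, run_feature_selection
from .marker_fitness import FitnessResult, MarkerTable, refine_fit_clusters
from .nmf_clustering import ClusterAssignment, RankEstimate, estimate_rank, provisional_assignments, sparse_nmf

logger = logging.getLogger("icgs2")


@dataclass
class PipelineConfig:
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    gene_filter: GeneFilterConfig = field(default_factory=lambda: GeneFilterConfig(protein_coding_only=False))
    marker_rho: float = 0.3
    min_markers: int = 2
    max_markers: int = 60
    rank: Optional[int] = None  # None = automatic Tracy-Widom estimation
    p_threshold: float = 0.001
    l1_weight: float = 0.0
    svm_C: float = 1.0
    min_genes_per_cell: Optional[int] = None  # outlier-cell filter, off by default
    seed: int = 0
    outdir: Optional[str] = None


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    downsampled_cells: List[str]
    guide3: Guide3Matrix
    rho_final: float
    rank_estimate: Optional[RankEstimate]
    rank: int
    provisional: ClusterAssignment
    fitness: FitnessResult
    marker_table: MarkerTable
    centroids: Centroids
    final: ClusterAssignment

    @property
    def n_fit_clusters(self) -> int:
        return len(self.fitness.fit_clusters)


def _write_artifacts(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    final = pd.DataFrame(
        {
            "cell": result.final.cell_ids,
            "cluster": result.final.labels,
            "svm_score": result.final.scores,
        }
    )
    final.to_csv(os.path.join(outdir, "final_assignments.tsv"), sep="\t", index=False)
    rows = []
    for cid in result.fitness.fit_clusters:
        for gene, rho in result.fitness.markers[cid]:
            rows.append({"gene": gene, "cluster": cid, "rho": rho})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "marker_genes.tsv"), sep="\t", index=False)
    g3 = pd.DataFrame(result.guide3.values, index=result.guide3.gene_ids, columns=result.guide3.cell_ids)
    g3.index.name = "Gene"
    module_row = pd.DataFrame(
        [[result.guide3.gene_to_module.get(g, -1) for g in result.guide3.gene_ids]],
        columns=result.guide3.gene_ids,
    )
    with open(os.path.join(outdir, "guide3.tsv"), "w") as fh:
        g3.to_csv(fh, sep="\t")
    module_row.T.rename(columns={0: "module"}).to_csv(
        os.path.join(outdir, "guide3_modules.tsv"), sep="\t"
    )
    if result.rank_estimate is not None:
        re_ = result.rank_estimate
        pd.DataFrame(
            {
                "eigenvalue": re_.eigenvalues,
                "tw_bound": re_.tw_bound,
                "significant": re_.eigenvalues > re_.tw_bound,
            }
        ).to_csv(os.path.join(outdir, "rank_report.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "downsampled_cells.txt"), "w") as fh:
        fh.write("\n".join(result.downsampled_cells) + "\n")
    cen = pd.DataFrame(result.centroids.centroids, index=result.centroids.feature_genes)
    cen.to_csv(os.path.join(outdir, "centroids.tsv"), sep="\t")


def run_pipeline(
    source, cfg: Optional[PipelineConfig] = None, input_format: str = "dense_tsv"
) -> PipelineResult:
    """Run the full workflow on a path or an in-memory ExpressionMatrix."""
    cfg = cfg or PipelineConfig()
    cfg.downsample.seed = cfg.seed

    if isinstance(source, ExpressionMatrix):
        m = source
    else:
        m = read_matrix(str(source), input_format)
        logger.info("read %d genes x %d cells from %s", m.n_genes, m.n_cells, source)

    if m.norm_state != NormState.cptt_log2:
        m = normalize_cptt(m)
    m = apply_gene_filters(m, cfg.gene_filter)
    logger.info("%d genes retained after class filters", m.n_genes)

    if cfg.min_genes_per_cell:
        expressed = (m.values > 1.0).sum(axis=0)  # genes with CPTT > 1
        keep = expressed >= cfg.min_genes_per_cell
        logger.info("outlier filter: dropping %d cells", int((~keep).sum()))
        m = m.subset_cells([c for c, k in zip(m.cell_ids, keep) if k])

    selected = downsample_cells(m, cfg.downsample)
    logger.info("downsampled %d -> %d cells", m.n_cells, len(selected))
    m_ds = m.subset_cells(selected)

    guide3, rho_final = run_feature_selection(m_ds, cfg.correlation)
    logger.info(
        "feature selection: %d genes, %d cells, final rho %.2f",
        guide3.n_genes, guide3.n_cells, rho_final,
    )

    rank_estimate = None
    if cfg.rank is not None:
        rank = cfg.rank
        logger.info("user-forced rank: %d", rank)
    else:
        rank_estimate = estimate_rank(guide3, cfg.p_threshold)
        rank = rank_estimate.rank
        logger.info(
            "rank estimation: %d significant eigenvalues -> rank %d",
            rank_estimate.k_significant, rank,
        )

    factorization = sparse_nmf(guide3, rank, l1_weight=cfg.l1_weight)
    provisional = provisional_assignments(factorization, guide3.cell_ids)

    fitness, fit_assignment, marker_table = refine_fit_clusters(
        m_ds,
        provisional,
        fitness_rho=rho_final,
        marker_rho=cfg.marker_rho,
        min_markers=cfg.min_markers,
        max_markers=cfg.max_markers,
    )
    for cid, reason in fitness.dropped.items():
        logger.info("cluster %d dropped: %s", cid, reason)
    logger.info("%d fit clusters", len(fitness.fit_clusters))

    centroids = compute_centroids(m_ds, fitness, fit_assignment)
    model = train_classifier(m_ds, fitness, fit_assignment, C=cfg.svm_C)
    final = assign_all_cells(model, m)

    result = PipelineResult(
        normalized=m,
        downsampled_cells=selected,
        guide3=guide3,
        rho_final=rho_final,
        rank_estimate=rank_estimate,
        rank=rank,
        provisional=provisional,
        fitness=fitness,
        marker_table=marker_table,
        centroids=centroids,
        final=final,
    )
    if cfg.outdir:
        _write_artifacts(result, cfg.outdir)
    return result
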