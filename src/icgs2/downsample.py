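"""Step 1 — intelligent downsampling of cells with PageRank.

For datasets above ``downsample_cutoff`` cells a k-nearest-neighbour graph is
built over the cells (restricted to the top dispersion genes) and the cells
with the highest PageRank scores are kept. Because every cell links only to
its k nearest neighbours, members of small transcriptionally distinct
populations form tight, mutually-linked neighbourhoods and retain high
PageRank scores, so rare populations survive the downsampling. Above
``louvain_threshold`` cells, Louvain community detection first reduces the
graph to ``louvain_target`` community-representative cells (the members with
the smallest summed intra-community Euclidean distance), and PageRank then
runs on a graph rebuilt over the representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import pairwise_distances_chunked
from sklearn.neighbors import NearestNeighbors

from .core_io import ExpressionMatrix, GeneFilterConfig, NormState, delog_cptt, gene_class_mask


@dataclass
class DownsampleConfig:
    n_dispersion_genes: int = 500
    knn_k: int = 10
    downsample_cutoff: int = 2500
    louvain_threshold: int = 15000
    louvain_target: Optional[int] = None  # default: downsample_cutoff * 4
    louvain_resolution: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.louvain_target is None:
            self.louvain_target = self.downsample_cutoff * 4
        if self.downsample_cutoff > self.louvain_target:
            raise ValueError("downsample_cutoff must be <= louvain_target")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class CellGraph:
    """Directed kNN graph over cells with optional PageRank/community data."""

    cell_ids: List[str]
    edges: List[tuple]  # (cell, neighbour) pairs
    pagerank: Optional[Dict[str, float]] = None
    communities: Optional[Dict[str, int]] = None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.cell_ids)
        g.add_edges_from(self.edges)
        return g


def gene_dispersion(m: ExpressionMatrix) -> Dict[str, float]:
    """Variance-to-mean ratio per gene, the dispersion used to rank genes.

    Computed on the count scale: raw counts directly, or de-logged CPTT when
    the matrix is normalized. Sample variance (n-1). Zero-mean genes score 0.
    """
    if m.n_cells < 2:
        raise ValueError("dispersion requires at least 2 cells")
    vals = delog_cptt(m.values) if m.norm_state == NormState.cptt_log2 else m.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return dict(zip(m.gene_ids, disp))


def select_dispersion_genes(
    scores: Dict[str, float],
    n: int = 500,
    filter_cfg: Optional[GeneFilterConfig] = None,
) -> List[str]:
    """The n highest-dispersion genes after gene-class exclusions.

    Mitochondrial, L/S ribosomal and immunoglobulin symbols are excluded to
    minimise batch and donor effects. Ties break lexicographically.
    """
    if not scores:
        raise ValueError("empty dispersion scores")
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = filter_cfg or GeneFilterConfig(protein_coding_only=False)
    genes = list(scores)
    keep = gene_class_mask(genes, cfg)
    eligible = [g for g, k in zip(genes, keep) if k]
    eligible.sort(key=lambda g: (-scores[g], g))
    return eligible[:n]


def build_knn_graph(m: ExpressionMatrix, genes: Sequence[str], k: int = 10) -> CellGraph:
    """Directed edges from each cell to its k nearest cells (Euclidean).

    Distances are computed in the space of the selected genes; k is capped at
    n_cells - 1 with a warning.
    """
    if m.n_cells < 2:
        raise ValueError("kNN graph requires at least 2 cells")
    sub = m.subset_genes(genes)
    if k > m.n_cells - 1:
        warnings.warn(f"k={k} exceeds n_cells-1; capping at {m.n_cells - 1}")
        k = m.n_cells - 1
    X = np.ascontiguousarray(sub.values.T, dtype=np.float32)  # cells x genes
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    cells = sub.cell_ids
    edges = []
    for i, row in enumerate(idx):
        neighbours = [j for j in row if j != i][:k]
        edges.extend((cells[i], cells[j]) for j in neighbours)
    return CellGraph(cell_ids=list(cells), edges=edges)


def pagerank_scores(g: CellGraph, damping: float = 0.85, tol: float = 1e-8, max_iter: int = 200) -> CellGraph:
    """Populate PageRank scores (damping 0.85, scores sum to 1)."""
    if not g.edges:
        raise ValueError("PageRank requires a graph with at least one edge")
    try:
        # networkx's stopping rule is (L1 residual) < N * tol; divide by N so
        # `tol` bounds the total residual of the score vector
        n = len(g.cell_ids)
        pr = nx.pagerank(g.to_networkx(), alpha=damping, tol=tol / max(n, 1), max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"PageRank failed to converge within {max_iter} iterations") from exc
    g.pagerank = dict(pr)
    return g


def louvain_partition(g: CellGraph, resolution: float = 0.0, seed: int = 0) -> CellGraph:
    """Louvain community labels; edges are treated as undirected.

    Resolution 0 is read as "the most granular cut of the Louvain
    dendrogram": the first level of the partition sequence, i.e. the smallest
    communities, before any aggregation passes merge them. Positive values
    run standard modularity Louvain at that resolution.
    """
    und = g.to_networkx().to_undirected()
    if und.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        first_level = next(nx.community.louvain_partitions(und, resolution=1.0, seed=seed))
        parts = first_level
    else:
        parts = nx.community.louvain_communities(und, resolution=resolution, seed=seed)
    # stable community ids: order communities by their smallest cell id
    parts = sorted((sorted(p) for p in parts), key=lambda p: p[0])
    g.communities = {c: i for i, members in enumerate(parts) for c in members}
    return g


def _central_members(X: np.ndarray, quota: int) -> np.ndarray:
    """Indices of the `quota` rows with smallest summed distance to all rows."""
    sums = np.zeros(X.shape[0])
    start = 0
    for chunk in pairwise_distances_chunked(X, metric="euclidean", working_memory=256):
        sums[start : start + chunk.shape[0]] = chunk.sum(axis=1)
        start += chunk.shape[0]
    order = np.lexsort((np.arange(len(sums)), sums))  # distance, then index
    return order[:quota]


def community_representatives(
    m: ExpressionMatrix, g: CellGraph, s: int, genes: Optional[Sequence[str]] = None
) -> List[str]:
    """Most central members of each Louvain community, quota floor(s/n) each.

    Community i contributes m_i = min(c_i, floor(s/n)) cells, the members
    with the smallest summed Euclidean distance to their co-members, so that
    rare and abundant communities are represented near-equally.
    """
    if g.communities is None:
        raise ValueError("communities not populated; run louvain_partition first")
    sub = m.subset_genes(genes) if genes is not None else m
    col = {c: i for i, c in enumerate(sub.cell_ids)}
    n_comm = len(set(g.communities.values()))
    quota = s // n_comm
    selected: List[str] = []
    by_comm: Dict[int, List[str]] = {}
    for cell, comm in g.communities.items():
        by_comm.setdefault(comm, []).append(cell)
    for comm in sorted(by_comm):
        members = sorted(by_comm[comm], key=lambda c: col[c])
        if len(members) == 1:
            selected.extend(members)
            continue
        m_i = min(len(members), quota)
        if m_i == 0:
            continue
        X = sub.values[:, [col[c] for c in members]].T.astype(np.float32)
        picks = _central_members(X, m_i)
        selected.extend(members[i] for i in picks)
    return selected


def downsample_cells(m: ExpressionMatrix, cfg: Optional[DownsampleConfig] = None) -> List[str]:
    """Select <= downsample_cutoff representative cells.

    n <= cutoff: all cells. cutoff < n <= louvain_threshold: PageRank on the
    full kNN graph, top-cutoff cells. n > louvain_threshold: Louvain
    representatives down to louvain_target cells, kNN graph rebuilt on the
    representatives, then PageRank to cutoff. PageRank ties break by cell id.
    """
    cfg = cfg or DownsampleConfig()
    if m.n_cells <= cfg.downsample_cutoff:
        return list(m.cell_ids)

    disp = gene_dispersion(m)
    genes = select_dispersion_genes(disp, cfg.n_dispersion_genes)
    graph = build_knn_graph(m, genes, cfg.knn_k)

    if m.n_cells > cfg.louvain_threshold:
        graph = louvain_partition(graph, cfg.louvain_resolution, cfg.seed)
        reps = community_representatives(m, graph, cfg.louvain_target, genes)
        order = {c: i for i, c in enumerate(m.cell_ids)}
        if len(reps) > cfg.downsample_cutoff:
            m = m.subset_cells(sorted(reps, key=order.get))
            graph = build_knn_graph(m, genes, cfg.knn_k)
        else:
            return sorted(reps, key=order.get)

    graph = pagerank_scores(graph)
    ranked = sorted(graph.cell_ids, key=lambda c: (-graph.pagerank[c], c))
    chosen = set(ranked[: cfg.downsample_cutoff])
    return [c for c in m.cell_ids if c in chosen]
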