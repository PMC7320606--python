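"""Step 2 — iterative correlation-based feature selection (ICGS).

Rather than ranking genes by marginal variance alone, genes are selected by
their membership in *correlated modules*: a gene is kept only when it has
enough correlated partners at a Pearson-rho threshold that is automatically
raised (0.2, +0.1, ...) until the retained set is of workable size. Retained
genes are grouped into modules by hybrid (HOPACH-style) clustering, each
module is summarised by a guide gene (the module medoid by mean
intra-module correlation), cell-cycle-driven modules are excluded, and a
supervised correlation against the guide genes builds the final feature
matrix ("Guide3") whose cells are ordered by hybrid clustering. Three
rounds of module discovery / guide expansion are run by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import ExpressionMatrix

# ---------------------------------------------------------------------------
# configuration


@dataclass
class CorrelationConfig:
    rho_start: float = 0.2
    rho_step: float = 0.1
    max_correlated_genes: int = 5000
    fold_threshold: float = 4.0
    min_cells_at_fold: int = 3
    min_partners: int = 4
    exclude_cell_cycle: bool = False
    cell_cycle_list: frozenset = frozenset()
    tf_list: frozenset = frozenset()  # optional transcription-factor bias
    n_rounds: int = 3
    cell_metric: str = "cosine"  # hybrid-clustering metric for cells

    def __post_init__(self) -> None:
        if not (0 < self.rho_start < 1):
            raise ValueError("rho_start must be in (0, 1)")
        if self.rho_step <= 0:
            raise ValueError("rho_step must be positive")


@dataclass
class GeneModule:
    id: int
    genes: List[str]
    guide: Optional[str] = None


@dataclass
class Guide3Matrix:
    """Feature-selected genes x downsampled cells, input to the SNMF stage."""

    gene_ids: List[str]
    cell_ids: List[str]  # ordered by the final hybrid clustering
    values: np.ndarray  # cptt_log2 scale
    gene_to_module: Dict[str, int]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# variable-gene (fold) filter


def variable_gene_filter(m: ExpressionMatrix, cfg: Optional[CorrelationConfig] = None) -> List[str]:
    """Genes whose expression spans >= fold_threshold fold robustly.

    On the log2 scale, a gene passes when its min_cells_at_fold-th highest
    value exceeds the max(0, min_cells_at_fold-th lowest) by
    log2(fold_threshold) — i.e. at least that many cells sit fold-fold above
    the (pseudocounted) baseline. Constant genes never pass.
    """
    cfg = cfg or CorrelationConfig()
    k = cfg.min_cells_at_fold
    vals = m.values
    if vals.shape[1] < 2 * k:
        raise ValueError(f"need at least {2 * k} cells for the fold filter")
    srt = np.sort(vals, axis=1)
    nth_low = srt[:, k - 1]
    nth_high = srt[:, -k]
    ratio = np.exp2(nth_high - np.maximum(nth_low, 0.0))
    nonconstant = vals.std(axis=1) > 0
    keep = (ratio >= cfg.fold_threshold) & nonconstant
    genes = [g for g, f in zip(m.gene_ids, keep) if f]
    if not genes:
        raise ValueError(
            "no gene passes the fold filter; lower fold_threshold or check normalization"
        )
    return genes


# ---------------------------------------------------------------------------
# distance matrices and deterministic k-medoids (HOPACH building blocks)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distances between rows; degenerate rows get distance 1."""
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        sq = (X * X).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        return np.sqrt(np.maximum(d2, 0.0))
    if metric == "correlation":
        X = X - X.mean(axis=1, keepdims=True)
    elif metric != "cosine":
        raise ValueError(f"unknown metric {metric!r}")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (X / safe[:, None]) @ (X / safe[:, None]).T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


_EXHAUSTIVE_LIMIT = 30000  # medoid subsets to enumerate before falling back


def _kmedoids(D: np.ndarray, k: int) -> Tuple[List[int], np.ndarray]:
    """Deterministic k-medoids on a distance matrix.

    Small instances are solved exactly by enumerating all medoid subsets
    (first subset in combination order wins ties); larger ones use
    farthest-point seeding from the global medoid followed by Voronoi
    iteration. Returns (medoid indices, labels).
    """
    n = D.shape[0]
    if k >= n:
        return list(range(n)), np.arange(n)
    from math import comb

    if comb(n, k) <= _EXHAUSTIVE_LIMIT:
        best_cost, best = np.inf, None
        for medoids in itertools.combinations(range(n), k):
            cost = D[list(medoids)].min(axis=0).sum()
            if cost < best_cost - 1e-12:
                best_cost, best = cost, list(medoids)
        medoids = best
    else:
        first = int(np.lexsort((np.arange(n), D.sum(axis=1)))[0])  # global medoid
        medoids = [first]
        mind = D[first].copy()
        while len(medoids) < k:
            nxt = int(np.lexsort((np.arange(n), -mind))[0])  # farthest point
            medoids.append(nxt)
            mind = np.minimum(mind, D[nxt])
        medoids = sorted(medoids)
        for _ in range(25):  # Voronoi refinement to a fixed point
            labels = np.argmin(D[medoids], axis=0)
            new = []
            for j in range(len(medoids)):
                members = np.where(labels == j)[0]
                if len(members) == 0:
                    new.append(medoids[j])
                    continue
                intra = D[np.ix_(members, members)].sum(axis=0)
                new.append(int(members[np.lexsort((members, intra))[0]]))
            new = sorted(set(new))
            while len(new) < k:  # re-seed collapsed medoids deterministically
                mind = D[new].min(axis=0)
                cand = int(np.lexsort((np.arange(n), -mind))[0])
                if cand in new:
                    break
                new.append(cand)
                new = sorted(new)
            if new == medoids:
                break
            medoids = new
    labels = np.argmin(D[medoids], axis=0)
    return list(medoids), labels


def _split_silhouette(D: np.ndarray, members: np.ndarray) -> float:
    """Median silhouette of a cluster's members under its best 2-way split.

    Low values mean the cluster resists further splitting (homogeneous).
    Clusters too small to split score 1.0 (worst), so partitions that
    shed singletons and pairs are not rewarded.
    """
    if len(members) < 3:
        return 1.0
    sub = D[np.ix_(members, members)]
    _, lab = _kmedoids(sub, 2)
    if len(set(lab)) < 2:
        return 0.0
    sils = []
    for i in range(len(members)):
        own = lab == lab[i]
        other = ~own
        a = sub[i, own].sum() / max(own.sum() - 1, 1)
        b = sub[i, other].mean()
        denom = max(a, b)
        sils.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.median(sils))


def _median_split_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for lab in np.unique(labels):
        vals.append(_split_silhouette(D, np.where(labels == lab)[0]))
    return float(np.median(vals))


def _partition_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Median standard silhouette of a partition; singleton members score 0."""
    sils = []
    uniq = np.unique(labels)
    for i in range(len(labels)):
        own = np.where(labels == labels[i])[0]
        if len(own) == 1:
            sils.append(0.0)
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, labels == u].mean() for u in uniq if u != labels[i])
        denom = max(a, b)
        sils.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.median(sils))


@dataclass
class HybridClustering:
    """Ordered partition from HOPACH-style clustering."""

    clusters: List[List[int]]  # ordered clusters of ordered item indices
    labels: np.ndarray  # item -> cluster id (order of `clusters`)
    order: List[int]  # flat item ordering

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _order_children(D: np.ndarray, children: List[np.ndarray], medoids: List[int]) -> List[int]:
    """Greedy chain: start at the child holding the lowest index, then hop to
    the nearest unvisited medoid."""
    starts = [int(c.min()) for c in children]
    current = int(np.argmin(starts))
    order = [current]
    remaining = set(range(len(children))) - {current}
    while remaining:
        dists = sorted((D[medoids[current], medoids[j]], j) for j in remaining)
        current = dists[0][1]
        order.append(current)
        remaining.remove(current)
    return order


def _pair_silhouette(D: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Median two-cluster silhouette of the members of clusters a and b."""
    sils = []
    for own, other in ((a, b), (b, a)):
        if len(own) == 1:
            sils.append(0.0)  # singleton convention: no intra-cluster evidence
            continue
        Din = D[np.ix_(own, own)]
        Dout = D[np.ix_(own, other)]
        for i in range(len(own)):
            ai = Din[i].sum() / (len(own) - 1)
            bi = Dout[i].mean()
            denom = max(ai, bi)
            sils.append(0.0 if denom == 0 else (bi - ai) / denom)
    return float(np.median(sils))


_MIN_SEPARATION = 0.15  # median-silhouette floor for accepting/keeping a split


def _min_separation(n: int) -> float:
    """Separation floor, raised for small nodes: silhouettes of arbitrary
    splits inflate roughly as 1/sqrt(n) at small sample size."""
    return max(_MIN_SEPARATION, 1.5 / np.sqrt(max(n, 1)))


def _collapse(
    D: np.ndarray,
    children: List[np.ndarray],
    medoids: List[int],
    min_separation: Optional[float] = None,
):
    """Merge adjacent siblings that are not meaningfully separated.

    Two neighbouring clusters collapse when the median silhouette of their
    members, judged between just the two of them, falls below
    ``min_separation`` — the hybrid "collapsing" step that undoes
    over-partitioning of homogeneous regions.
    """
    children = list(children)
    medoids = list(medoids)
    merged = True
    while merged and len(children) > 1:
        merged = False
        for i in range(len(children) - 1):
            pair_n = len(children[i]) + len(children[i + 1])
            floor = min_separation if min_separation is not None else _min_separation(pair_n)
            if _pair_silhouette(D, children[i], children[i + 1]) < floor:
                joint = np.concatenate([children[i], children[i + 1]])
                intra = D[np.ix_(joint, joint)].sum(axis=0)
                med = int(joint[np.lexsort((joint, intra))[0]])
                children[i : i + 2] = [joint]
                medoids[i : i + 2] = [med]
                merged = True
                break
    return children, medoids


def _hopach_recurse(D: np.ndarray, items: np.ndarray, depth: int, max_depth: int, max_k: int) -> List[np.ndarray]:
    n = len(items)
    if n < 3 or depth >= max_depth:
        return [items]
    sub = D[np.ix_(items, items)]
    if sub.max() <= 1e-12:  # all identical
        return [items]
    best = None  # (mss, k, labels, medoids)
    for k in range(2, min(max_k, n - 1) + 1):
        medoids, labels = _kmedoids(sub, k)
        if len(np.unique(labels)) < 2:
            continue
        mss = _median_split_silhouette(sub, labels)
        if best is None or mss < best[0] - 1e-12:
            best = (mss, k, labels, medoids)
    if best is None:
        return [items]
    _, k, labels, medoids = best
    # accept the split only when the partition is genuinely separated;
    # otherwise the node is homogeneous and becomes a leaf
    if _partition_silhouette(sub, labels) < _min_separation(n):
        return [items]
    uniq = np.unique(labels)
    children = [np.where(labels == u)[0] for u in uniq]
    child_medoids = [medoids[u] for u in uniq]
    order = _order_children(sub, children, child_medoids)
    children = [children[j] for j in order]
    child_medoids = [child_medoids[j] for j in order]
    children, child_medoids = _collapse(sub, children, child_medoids)
    out: List[np.ndarray] = []
    for child in children:
        out.extend(_hopach_recurse(D, items[child], depth + 1, max_depth, max_k))
    return out


def hybrid_cluster(
    matrix: np.ndarray,
    axis: str = "genes",
    metric: str = "correlation",
    max_depth: int = 3,
    max_k: int = 9,
) -> HybridClustering:
    """HOPACH-style hierarchical ordered partitioning of rows or columns.

    At each node, candidate 2..max_k medoid partitions are scored by median
    split silhouette (lower = children more homogeneous) and the best is
    kept; children are ordered by medoid proximity, indistinguishable
    siblings are collapsed, and partitioning recurses to ``max_depth``.
    Fully deterministic: exact medoid search on small nodes, fixed seeding
    and tie rules elsewhere.
    """
    X = matrix if axis == "genes" else matrix.T
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _distance_matrix(X, metric)
    leaves = _hopach_recurse(D, np.arange(n), 0, max_depth, max_k)
    clusters = []
    for leaf in leaves:
        med = int(leaf[np.lexsort((leaf, D[np.ix_(leaf, leaf)].sum(axis=0)))[0]])
        ordered = sorted(leaf, key=lambda i: (D[med, i], i))
        clusters.append([int(i) for i in ordered])
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    order = [i for c in clusters for i in c]
    return HybridClustering(clusters=clusters, labels=labels, order=order)


# ---------------------------------------------------------------------------
# correlated-module discovery with auto-tuned rho


def _row_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows correlate 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    corr = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def correlated_gene_search(
    m: ExpressionMatrix,
    genes: Sequence[str],
    cfg: Optional[CorrelationConfig] = None,
) -> Tuple[List[GeneModule], float]:
    """Find correlated gene modules, auto-incrementing the rho cutoff.

    All-pairs Pearson rho among the candidate genes; a gene is retained when
    it has >= min_partners partners at rho >= threshold. While more than
    max_correlated_genes survive, the threshold is raised by rho_step and
    the selection repeated. Retained genes are partitioned into modules by
    hybrid clustering on the gene axis (correlation metric).
    """
    cfg = cfg or CorrelationConfig()
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate genes")
    sub = m.subset_genes(genes)
    corr = _row_corr(sub.values)
    np.fill_diagonal(corr, -np.inf)  # a gene is not its own partner
    rho = cfg.rho_start
    while True:
        partners = (corr >= rho - 1e-12).sum(axis=1)
        retained = partners >= cfg.min_partners
        count = int(retained.sum())
        if count <= cfg.max_correlated_genes:
            break
        rho = round(rho + cfg.rho_step, 10)
        if rho > 0.9:
            raise ValueError(
                f"rho exceeded 0.9 with {count} correlated genes still above the "
                f"cap of {cfg.max_correlated_genes}"
            )
    if count == 0:
        raise ValueError(
            f"no gene has {cfg.min_partners} partners at rho {rho}; lower rho_start"
        )
    kept = [g for g, r in zip(genes, retained) if r]
    if len(kept) < 2:
        modules = [GeneModule(id=0, genes=kept)]
        return modules, rho
    kept_idx = np.where(retained)[0]
    clustering = hybrid_cluster(sub.values[kept_idx], axis="genes", metric="correlation")
    modules = [
        GeneModule(id=cid, genes=[kept[i] for i in members])
        for cid, members in enumerate(clustering.clusters)
    ]
    return modules, rho


def select_guide_genes(
    modules: Sequence[GeneModule],
    m: ExpressionMatrix,
    cfg: Optional[CorrelationConfig] = None,
) -> List[str]:
    """Pick one guide gene per module: the module medoid by mean intra-module
    correlation.

    Cell-cycle genes are never chosen as guides; when exclude_cell_cycle is
    set, a module whose medoid *is* a cell-cycle gene is dropped entirely
    (its coherence is cell-cycle-driven). With a tf_list supplied, guides
    are preferentially drawn from transcription factors.
    """
    cfg = cfg or CorrelationConfig()
    cc = set(cfg.cell_cycle_list)
    guides: List[str] = []
    for module in modules:
        if not module.genes:
            continue
        if len(module.genes) == 1:
            g = module.genes[0]
            if g in cc:
                if cfg.exclude_cell_cycle:
                    continue
                continue  # a cell-cycle gene is never a guide
            module.guide = g
            guides.append(g)
            continue
        sub = m.subset_genes(module.genes)
        corr = _row_corr(sub.values)
        np.fill_diagonal(corr, np.nan)
        mean_rho = np.nanmean(corr, axis=1)
        order = sorted(range(len(module.genes)), key=lambda i: (-mean_rho[i], module.genes[i]))
        medoid = module.genes[order[0]]
        if medoid in cc and cfg.exclude_cell_cycle:
            continue  # cell-cycle-driven module
        pool = [i for i in order if module.genes[i] not in cc]
        if cfg.tf_list:
            tf_pool = [i for i in pool if module.genes[i] in cfg.tf_list]
            pool = tf_pool or pool
        if not pool:
            continue
        module.guide = module.genes[pool[0]]
        guides.append(module.guide)
    if not guides:
        raise ValueError("all modules dropped during guide selection")
    return guides


def guide3_matrix(
    m: ExpressionMatrix,
    guides: Sequence[str],
    candidate_genes: Sequence[str],
    rho_final: float,
    cfg: Optional[CorrelationConfig] = None,
    guide_to_module: Optional[Dict[str, int]] = None,
) -> Guide3Matrix:
    """Supervised correlation against the guides -> the Guide3 matrix.

    Every candidate gene with Pearson rho >= rho_final to at least one guide
    is included (guides always include themselves) and attributed to the
    module of its best-correlated guide; cells are ordered by hybrid
    clustering (cosine by default).
    """
    cfg = cfg or CorrelationConfig()
    if len(guides) < 2:
        raise ValueError("need at least 2 guide genes")
    guide_to_module = guide_to_module or {g: i for i, g in enumerate(guides)}
    cand = list(dict.fromkeys(list(candidate_genes)))
    sub = m.subset_genes(cand)
    gsub = m.subset_genes(list(guides))

    def _unit_rows(X):
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        U = Xc / safe[:, None]
        U[norms == 0] = 0.0
        return U

    rho = _unit_rows(sub.values) @ _unit_rows(gsub.values).T  # cand x guides
    best_guide = np.argmax(rho, axis=1)
    best_rho = rho[np.arange(len(cand)), best_guide]
    include = best_rho >= rho_final - 1e-12
    for i, g in enumerate(cand):  # guides are in by construction
        if g in guide_to_module:
            include[i] = True
    sel = [
        (guide_to_module[guides[best_guide[i]]], -best_rho[i], cand[i])
        for i in np.where(include)[0]
    ]
    sel.sort()
    genes = [g for _, _, g in sel]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes survive the guide correlation")
    gene_to_module = {g: mod for mod, _, g in sel}
    mat = m.subset_genes(genes)
    ordering = hybrid_cluster(mat.values, axis="cells", metric=cfg.cell_metric)
    cell_ids = [mat.cell_ids[i] for i in ordering.order]
    values = mat.values[:, ordering.order]
    return Guide3Matrix(gene_ids=genes, cell_ids=cell_ids, values=values, gene_to_module=gene_to_module)


def run_feature_selection(
    m: ExpressionMatrix, cfg: Optional[CorrelationConfig] = None
) -> Tuple[Guide3Matrix, float]:
    """Full Step-2 pipeline on the (downsampled, normalized) matrix.

    Fold filter -> n_rounds of (module discovery with auto-rho, guide
    selection, guide-correlation expansion) -> Guide3 matrix. Returns the
    Guide3 matrix and the final auto-tuned rho.
    """
    cfg = cfg or CorrelationConfig()
    variable = variable_gene_filter(m, cfg)
    current = variable
    rho_final = cfg.rho_start
    guides: List[str] = []
    guide_to_module: Dict[str, int] = {}
    for _ in range(max(cfg.n_rounds, 1)):
        modules, rho_final = correlated_gene_search(m, current, cfg)
        guides = select_guide_genes(modules, m, cfg)
        guide_to_module = {mod.guide: mod.id for mod in modules if mod.guide is not None}
        sub = m.subset_genes(variable)
        gsub = m.subset_genes(guides)
        rho = _row_corr(np.vstack([sub.values, gsub.values]))[: len(variable), len(variable):]
        best = rho.max(axis=1) if rho.size else np.zeros(len(variable))
        expanded = [g for g, r in zip(variable, best) if r >= rho_final - 1e-12]
        expanded = list(dict.fromkeys(expanded + list(guides)))
        if len(expanded) < max(cfg.min_partners + 1, 2):
            break
        current = expanded
    return (
        guide3_matrix(m, guides, current, rho_final, cfg, guide_to_module),
        rho_final,
    )
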