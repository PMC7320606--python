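"""Step 4 — marker-gene discovery (MarkerFinder) and cluster fitness.

Each candidate cluster is summarised by an idealized reference profile (1
for member cells, 0 otherwise); every gene is Pearson-correlated against
all references and attributed to its best-matching cluster. A cluster is
"fit" only when at least ``min_markers`` genes correlate with its reference
above the fitness rho cutoff (by default the auto-tuned rho from feature
selection) — clusters without uniquely expressed genes, such as doublet
artifacts mixing two real populations' programs, are dissolved, and their
cells are reassigned downstream by the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .nmf_clustering import ClusterAssignment


@dataclass
class MarkerTable:
    """Rows of (gene, cluster, rho): each gene assigned to its max-rho cluster."""

    table: pd.DataFrame  # columns: gene, cluster, rho

    def for_cluster(self, cluster: int) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster]


@dataclass
class FitnessResult:
    fit_clusters: List[int]
    markers: Dict[int, List[Tuple[str, float]]]  # cluster -> [(gene, rho)] desc
    dropped: Dict[int, str]  # cluster -> reason

    @property
    def marker_union(self) -> List[str]:
        seen = set()
        out = []
        for cid in self.fit_clusters:
            for g, _ in self.markers[cid]:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return sorted(out)


def marker_finder(m: ExpressionMatrix, a: ClusterAssignment) -> MarkerTable:
    """Correlate every gene with each cluster's idealized 0/1 reference.

    Constant (zero-variance) genes are skipped; ties in the max-rho
    assignment break toward the lower cluster id.
    """
    clusters = sorted(set(int(x) for x in a.labels))
    if len(clusters) < 2:
        raise ValueError("MarkerFinder requires at least 2 clusters")
    order = {c: i for i, c in enumerate(m.cell_ids)}
    lab = np.empty(m.n_cells, dtype=int)
    for cell, label in zip(a.cell_ids, a.labels):
        if cell not in order:
            raise ValueError(f"assigned cell {cell!r} absent from the matrix")
        lab[order[cell]] = label
    refs = np.stack([(lab == c).astype(float) for c in clusters])  # K x cells

    X = m.values
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    Rc = refs - refs.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(Rc, axis=1)
    valid = xn > 0
    rho = np.zeros((X.shape[0], len(clusters)))
    rho[valid] = (Xc[valid] / xn[valid][:, None]) @ (Rc / rn[:, None]).T
    np.clip(rho, -1.0, 1.0, out=rho)

    best = np.argmax(rho, axis=1)  # argmax takes the first (lowest) index on ties
    rows = [
        {"gene": g, "cluster": clusters[best[i]], "rho": rho[i, best[i]]}
        for i, g in enumerate(m.gene_ids)
        if valid[i]
    ]
    table = pd.DataFrame(rows, columns=["gene", "cluster", "rho"])
    return MarkerTable(table=table)


def fitness_filter(
    t: MarkerTable,
    fitness_rho: float,
    marker_rho: float = 0.3,
    min_markers: int = 2,
    max_markers: int = 60,
    clusters: Optional[Sequence[int]] = None,
) -> FitnessResult:
    """Drop clusters lacking unique markers; cap surviving marker lists.

    A cluster survives when >= min_markers of its genes reach
    rho >= fitness_rho; its marker list is the top max_markers genes with
    rho strictly > marker_rho (ties at the cap break by gene id).
    ``clusters`` is the full candidate universe — a cluster to which no gene
    was assigned at all is dropped, not silently ignored.
    """
    if t.table.empty:
        raise ValueError("empty marker table")
    fit, dropped, markers = [], {}, {}
    universe = sorted(set(clusters)) if clusters is not None else sorted(t.table["cluster"].unique())
    for cluster in set(universe) - set(t.table["cluster"].unique()):
        dropped[int(cluster)] = "no gene assigned to this cluster"
    for cluster, grp in t.table.groupby("cluster"):
        if cluster not in universe:
            continue
        n_at_cutoff = int((grp["rho"] >= fitness_rho - 1e-12).sum())
        if n_at_cutoff < min_markers:
            dropped[int(cluster)] = (
                f"only {n_at_cutoff} marker(s) at rho >= {fitness_rho:g} "
                f"(need {min_markers})"
            )
            continue
        fit.append(int(cluster))
        qual = grp[grp["rho"] > marker_rho].sort_values(
            ["rho", "gene"], ascending=[False, True]
        )
        top = qual.head(max_markers)
        markers[int(cluster)] = list(zip(top["gene"], top["rho"]))
    if not fit:
        raise ValueError(
            "no cluster passed the fitness filter; consider forcing a lower rank"
        )
    return FitnessResult(fit_clusters=sorted(fit), markers=markers, dropped=dropped)


def refine_fit_clusters(
    m: ExpressionMatrix,
    a: ClusterAssignment,
    fitness_rho: float,
    marker_rho: float = 0.3,
    min_markers: int = 2,
    max_markers: int = 60,
    max_rounds: int = 10,
) -> Tuple[FitnessResult, ClusterAssignment, MarkerTable]:
    """Iterate MarkerFinder + fitness until the fit-cluster set is stable.

    After a cluster is dropped, markers are recomputed on the cells of the
    remaining clusters only (a dropped cluster's cells no longer dilute the
    references); iteration ends when no further cluster is dropped. Returns
    the fitness result, the assignment restricted to fit-cluster cells
    (stage="fit") and the final marker table.
    """
    current = a
    all_dropped: Dict[int, str] = {}
    for _ in range(max_rounds):
        table = marker_finder(m.subset_cells(current.cell_ids), current)
        fr = fitness_filter(
            table, fitness_rho, marker_rho, min_markers, max_markers,
            clusters=sorted(set(int(x) for x in current.labels)),
        )
        if not fr.dropped:
            fr.dropped = all_dropped
            fit = ClusterAssignment(
                cell_ids=list(current.cell_ids), labels=current.labels.copy(), stage="fit"
            )
            return fr, fit, table
        all_dropped.update(fr.dropped)
        keep = np.isin(current.labels, fr.fit_clusters)
        if len(fr.fit_clusters) < 2:  # cannot recompute references with <2 clusters
            fr.dropped = all_dropped
            current = ClusterAssignment(
                cell_ids=[c for c, k in zip(current.cell_ids, keep) if k],
                labels=current.labels[keep],
                stage="fit",
            )
            return fr, current, table
        current = ClusterAssignment(
            cell_ids=[c for c, k in zip(current.cell_ids, keep) if k],
            labels=current.labels[keep],
            stage="fit",
        )
    warnings.warn(f"fitness refinement did not stabilise in {max_rounds} rounds")
    fr.dropped = all_dropped
    return fr, current, table
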