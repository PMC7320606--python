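"""Step 5 — assign every cell in the full dataset to a fit cluster.

The downsampled cells of the fit clusters, restricted to the union of the
fit clusters' marker genes, train a multiclass linear-kernel SVM
(one-vs-rest, C=1). The model is then applied to all cells of the original
dataset — including those removed by downsampling — yielding the final
cell-to-cluster assignment with per-cell decision scores. Cluster centroids
in marker space are exported for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from sklearn.svm import LinearSVC

from .core_io import ExpressionMatrix
from .marker_fitness import FitnessResult
from .nmf_clustering import ClusterAssignment


@dataclass
class Centroids:
    """cluster -> mean marker-space expression of its member cells."""

    feature_genes: List[str]
    centroids: Dict[int, np.ndarray]


@dataclass
class TrainedClassifier:
    feature_genes: List[str]
    classes: List[int]
    model: Optional[LinearSVC]  # None when a single class degenerates to a constant


def _marker_space(m: ExpressionMatrix, feature_genes: List[str]) -> np.ndarray:
    """cells x features matrix; marker genes missing from m are imputed as 0."""
    index = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in feature_genes if g not in index]
    if missing:
        warnings.warn(f"{len(missing)} marker genes absent from the matrix; imputed as 0")
    X = np.zeros((m.n_cells, len(feature_genes)))
    for j, g in enumerate(feature_genes):
        if g in index:
            X[:, j] = m.values[index[g], :]
    return X


def compute_centroids(m: ExpressionMatrix, fr: FitnessResult, a: ClusterAssignment) -> Centroids:
    """Arithmetic-mean centroid per fit cluster over the marker-gene union."""
    if not fr.fit_clusters:
        raise ValueError("no fit clusters")
    feature_genes = fr.marker_union
    X = _marker_space(m.subset_cells(a.cell_ids), feature_genes)
    centroids: Dict[int, np.ndarray] = {}
    for cid in fr.fit_clusters:
        members = np.asarray(a.labels) == cid
        if not members.any():
            warnings.warn(f"fit cluster {cid} has no assigned cells; dropped from centroids")
            continue
        centroids[cid] = X[members].mean(axis=0)
    return Centroids(feature_genes=feature_genes, centroids=centroids)


def train_classifier(
    m: ExpressionMatrix,
    fr: FitnessResult,
    a: ClusterAssignment,
    C: float = 1.0,
    max_iter: int = 10000,
) -> TrainedClassifier:
    """Linear-kernel SVM (one-vs-rest, C=1) on downsampled fit-cluster cells.

    Features are the union of the fit clusters' marker genes. A single
    surviving class degenerates to a constant labeling with a warning.
    """
    feature_genes = fr.marker_union
    keep = np.isin(np.asarray(a.labels), fr.fit_clusters)
    cells = [c for c, k in zip(a.cell_ids, keep) if k]
    labels = np.asarray(a.labels)[keep]
    classes = sorted(set(int(x) for x in labels))
    if not classes:
        raise ValueError("no training cells belong to fit clusters")
    if len(classes) == 1:
        warnings.warn("single fit cluster; classifier degenerates to a constant labeling")
        return TrainedClassifier(feature_genes=feature_genes, classes=classes, model=None)
    X = _marker_space(m.subset_cells(cells), feature_genes)
    model = LinearSVC(C=C, max_iter=max_iter, random_state=0)
    model.fit(X, labels)
    return TrainedClassifier(feature_genes=feature_genes, classes=classes, model=model)


def assign_all_cells(clf: TrainedClassifier, m_full: ExpressionMatrix) -> ClusterAssignment:
    """Apply the trained model to every cell of the full dataset.

    Returns a final-stage assignment whose label universe is the fit
    clusters; scores are the winning decision-function values (1.0 for the
    degenerate single-class model).
    """
    X = _marker_space(m_full, clf.feature_genes)
    if clf.model is None:
        labels = np.full(m_full.n_cells, clf.classes[0], dtype=int)
        scores = np.ones(m_full.n_cells)
    else:
        decision = clf.model.decision_function(X)
        if decision.ndim == 1:  # binary: one column, signed margin
            labels = np.where(decision >= 0, clf.model.classes_[1], clf.model.classes_[0])
            scores = np.abs(decision)
        else:
            best = np.argmax(decision, axis=1)
            labels = clf.model.classes_[best]
            scores = decision[np.arange(len(best)), best]
    return ClusterAssignment(
        cell_ids=list(m_full.cell_ids),
        labels=np.asarray(labels, dtype=int),
        stage="final",
        scores=np.asarray(scores, dtype=float),
    )
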