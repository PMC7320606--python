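"""Step 3 — rank estimation and sparse NMF clustering of the Guide3 matrix.

The number of clusters is not user-supplied: the Guide3 matrix is per-gene
z-scored, the eigenvalues of its cell-cell Gram matrix are compared against
the Tracy-Widom null for the largest eigenvalue of a white Wishart matrix,
and the SNMF rank is set to twice the number of significant eigenvalues
(floored at 2). Factorization uses NNDSVD initialization — a deterministic
SVD-based start — so repeated runs give identical results, with an optional
L1 penalty on H for sparsity; each cell's provisional cluster is the factor
with its largest basis weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import gamma
from sklearn.decomposition import NMF

from .feature_selection import Guide3Matrix

# Tracy-Widom (beta=1) upper-tail quantiles via the shifted-gamma
# approximation of Chiani (2014), J. Multivariate Analysis 129:69-81:
# TW1 ~ Gamma(k, theta) - alpha with the constants below.
_TW1_K = 46.44604884387337
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848007781128567


def tw1_quantile(p_upper: float) -> float:
    """Upper-tail quantile s with P(TW1 > s) = p_upper."""
    return float(gamma.ppf(1.0 - p_upper, _TW1_K, scale=_TW1_THETA) - _TW1_ALPHA)


@dataclass
class RankEstimate:
    eigenvalues: np.ndarray  # descending
    k_significant: int
    rank: int  # 2 * k_significant, floored at 2
    n_genes: int
    n_cells: int
    p_threshold: float
    tw_location: float
    tw_scale: float
    tw_bound: float  # eigenvalue significance cutoff on the raw scale


@dataclass
class Factorization:
    W: np.ndarray  # cells x rank, non-negative basis weights
    H: np.ndarray  # rank x genes, non-negative coefficients
    objective: float  # final Frobenius reconstruction error
    objective_initial: float  # error at the NNDSVD starting point
    n_iter: int


@dataclass
class ClusterAssignment:
    """cell -> cluster label (1-based ints) with a pipeline-stage tag."""

    cell_ids: List[str]
    labels: np.ndarray
    stage: str  # provisional | fit | final
    scores: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        return dict(zip(self.cell_ids, (int(x) for x in self.labels)))


def _zscore_genes(values: np.ndarray) -> np.ndarray:
    """Per-gene z-score; zero-variance genes are dropped with a warning."""
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before z-scoring")
    vals = values[keep]
    return (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]


def estimate_rank(guide3: Guide3Matrix, p_threshold: float = 0.001) -> RankEstimate:
    """Estimate the SNMF rank from Tracy-Widom-significant eigenvalues.

    With Z the g x c per-gene z-scored Guide3 matrix, the eigenvalues of
    Z'Z are tested against the largest-eigenvalue null for a white Wishart
    matrix with (g-1, c) degrees of freedom: location
    mu = (sqrt(g-1) + sqrt(c))^2 and scale
    sigma = (sqrt(g-1) + sqrt(c)) * (1/sqrt(g-1) + 1/sqrt(c))^(1/3).
    An eigenvalue is significant when (lambda - mu) / sigma exceeds the TW1
    quantile at p_threshold; the rank is max(2, 2 * #significant).
    """
    if guide3.n_genes < 3 or guide3.n_cells < 3:
        raise ValueError("rank estimation needs at least 3 genes and 3 cells")
    Z = _zscore_genes(guide3.values)
    g, c = Z.shape
    gram = Z.T @ Z  # c x c
    evals = np.linalg.eigvalsh(gram)[::-1]
    mu = (np.sqrt(g - 1) + np.sqrt(c)) ** 2
    sigma = (np.sqrt(g - 1) + np.sqrt(c)) * (1.0 / np.sqrt(g - 1) + 1.0 / np.sqrt(c)) ** (1.0 / 3.0)
    bound = mu + sigma * tw1_quantile(p_threshold)
    k_sig = int((evals > bound).sum())
    rank = max(2, 2 * k_sig)
    rank = min(rank, min(g, c))
    return RankEstimate(
        eigenvalues=evals,
        k_significant=k_sig,
        rank=rank,
        n_genes=g,
        n_cells=c,
        p_threshold=p_threshold,
        tw_location=mu,
        tw_scale=sigma,
        tw_bound=bound,
    )


def nndsvd_init(X: np.ndarray, rank: int) -> Tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (Boutsidis & Gallopoulos 2008).

    Deterministic: each SVD pair is split into its positive and negative
    parts and the dominant part is kept; zero entries stay zero ("plain"
    NNDSVD variant).
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, rank))
    H = np.zeros((rank, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        termp, termn = n_up * n_vp, n_un * n_vn
        if termp >= termn:
            sigma = termp
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * up / n_up
                H[j, :] = np.sqrt(S[j] * sigma) * vp / n_vp
        else:
            sigma = termn
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * un / n_un
                H[j, :] = np.sqrt(S[j] * sigma) * vn / n_vn
    return W, H


def sparse_nmf(
    guide3: Guide3Matrix,
    rank: int,
    l1_weight: float = 0.0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> Factorization:
    """NNDSVD-initialized sparse NMF of the (cells x genes) Guide3 matrix.

    Coordinate-descent NMF with an L1 penalty on H (weight ``l1_weight``,
    0 = plain NMF). Deterministic: the initialization is SVD-based and the
    solver visits coordinates in a fixed order, so identical inputs give
    identical factorizations.
    """
    X = guide3.values.T.copy()  # cells x genes
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(X.shape):
        raise ValueError(
            f"rank {rank} exceeds min(n_cells, n_genes) = {min(X.shape)}; reduce the rank"
        )
    if X.min() < 0:
        warnings.warn("negative entries clipped to 0 before NMF")
        X = np.maximum(X, 0.0)
    W0, H0 = nndsvd_init(X, rank)
    obj0 = float(np.linalg.norm(X - W0 @ H0, "fro"))
    model = NMF(
        n_components=rank,
        init="custom",
        solver="cd",
        beta_loss="frobenius",
        alpha_W=0.0,
        alpha_H=l1_weight,
        l1_ratio=1.0,
        tol=tol,
        max_iter=max_iter,
        shuffle=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled via n_iter_
        W = model.fit_transform(X, W=W0.copy(), H=H0.copy())
    H = model.components_
    obj = float(np.linalg.norm(X - W @ H, "fro"))
    return Factorization(W=W, H=H, objective=obj, objective_initial=obj0, n_iter=model.n_iter_)


def provisional_assignments(f: Factorization, cell_ids: List[str]) -> ClusterAssignment:
    """Label each cell by the factor with its largest W weight (1-based).

    Ties break toward the lowest factor index. A cell with an all-zero W
    row is assigned to the factor with the largest H-weighted reconstruction
    norm and flagged with a warning.
    """
    if f.W.shape[0] != len(cell_ids):
        raise ValueError("W row count does not match cell count")
    labels = np.argmax(f.W, axis=1) + 1
    zero_rows = np.where(~f.W.any(axis=1))[0]
    if len(zero_rows):
        fallback = int(np.argmax(np.linalg.norm(f.H, axis=1))) + 1
        labels[zero_rows] = fallback
        warnings.warn(f"{len(zero_rows)} cells had all-zero basis rows; assigned to factor {fallback}")
    scores = f.W.max(axis=1)
    return ClusterAssignment(cell_ids=list(cell_ids), labels=labels, stage="provisional", scores=scores)
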