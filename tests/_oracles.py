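"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check: pair counting
for the ARI, dense power iteration for PageRank, exhaustive enumeration for
community representatives.
"""

import itertools

import numpy as np


def brute_force_ari(a, b):
    """ARI by explicit agreement counting over all unordered cell pairs."""
    cells = sorted(a)
    pairs = list(itertools.combinations(cells, 2))
    n11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    n10 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] != b[j])
    n01 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] == b[j])
    total = len(pairs)
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def dense_pagerank(cells, edges, damping=0.85, iters=5000):
    """Dense power iteration with uniform teleport; dangling nodes spread
    their mass uniformly."""
    n = len(cells)
    idx = {c: i for i, c in enumerate(cells)}
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = 1.0
    out = A.sum(axis=1)
    P = np.where(out[:, None] > 0, A / np.where(out[:, None] > 0, out[:, None], 1), 1.0 / n)
    r = np.full(n, 1.0 / n)
    for _ in range(iters):
        r = (1 - damping) / n + damping * (P.T @ r)
    return dict(zip(cells, r / r.sum()))


def exhaustive_representative(X):
    """Index of the row minimizing the summed Euclidean distance to all rows."""
    best = (np.inf, None)
    for i in range(X.shape[0]):
        total = sum(np.linalg.norm(X[i] - X[j]) for j in range(X.shape[0]))
        if total < best[0] - 1e-12:
            best = (total, i)
    return best[1]
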