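"""Benchmarking metrics: ARI, cluster specificity, aggregate ARI,
donor-enrichment z-scores and downsampling retention reports.

Aggregate ARI rewards methods that split a reference population into
coherent sub-clusters: any test cluster with specificity > 75% for one
reference population (percentage of its cells falling inside it) is merged
into that population before pair-counting. Donor enrichment quantifies
batch effects as signed z-scores from one-sided Fisher-exact/hypergeometric
tests of each donor against each cluster. Retention reports measure how
many members of each true population survive a downsampling, compared with
simple random sampling (SRS) of matched size.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from sklearn.metrics import adjusted_rand_score

_Z_CAP = 38.0  # |z| cap; beyond this the normal tail underflows


def _check_universes(a: Mapping, b: Mapping) -> List:
    if set(a) != set(b):
        raise ValueError("label mappings cover different cell universes")
    return sorted(a)


def adjusted_rand_index(a: Mapping, b: Mapping) -> float:
    """Pair-counting adjusted Rand index between two labelings (same cells)."""
    cells = _check_universes(a, b)
    # factorize so labels may be any hashable (ints, strings, merged tuples)
    def codes(mapping):
        seen: dict = {}
        return [seen.setdefault(mapping[c], len(seen)) for c in cells]

    return float(adjusted_rand_score(codes(a), codes(b)))


def specificity_matrix(test: Mapping, ref: Mapping) -> pd.DataFrame:
    """s_ij = 100 * |cells in test cluster i and ref cluster j| / |i|."""
    cells = _check_universes(test, ref)
    df = pd.DataFrame({"test": [test[c] for c in cells], "ref": [ref[c] for c in cells]})
    counts = df.groupby(["test", "ref"]).size().unstack(fill_value=0)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty test cluster")
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def aggregate_ari(test: Mapping, ref: Mapping, spec_threshold: float = 75.0) -> float:
    """ARI after merging test clusters highly specific to one reference.

    Every test cluster whose specificity for some reference cluster is
    strictly above ``spec_threshold`` (percent) is relabeled to that
    reference's merged id (max specificity wins; ties go to the lower
    reference id); the ARI is then computed on the merged labels.
    """
    spec = specificity_matrix(test, ref)
    merge: Dict = {}
    for i, row in spec.iterrows():
        best = row.max()
        if best > spec_threshold:
            target = sorted(j for j in spec.columns if row[j] == best)[0]
            merge[i] = ("merged", target)
    merged_test = {c: merge.get(test[c], test[c]) for c in test}
    return adjusted_rand_index(merged_test, ref)


def donor_enrichment(assignment: Mapping, donors: Mapping) -> pd.DataFrame:
    """Signed enrichment z-scores of each donor in each cluster.

    One-sided hypergeometric (Fisher-exact) tail probabilities are mapped
    through the standard-normal inverse: positive z = the donor is
    over-represented in the cluster, negative = under-represented;
    |z| is capped at 38.
    """
    cells = _check_universes(assignment, donors)
    clusters = sorted(set(assignment[c] for c in cells))
    donor_ids = sorted(set(donors[c] for c in cells))
    if len(donor_ids) < 2:
        warnings.warn("single donor; all enrichment z-scores are 0")
        return pd.DataFrame(0.0, index=clusters, columns=donor_ids)
    N = len(cells)
    out = pd.DataFrame(0.0, index=clusters, columns=donor_ids)
    for cl in clusters:
        members = [c for c in cells if assignment[c] == cl]
        n = len(members)
        for d in donor_ids:
            K = sum(1 for c in cells if donors[c] == d)
            k = sum(1 for c in members if donors[c] == d)
            expected = n * K / N
            if k >= expected:
                p = hypergeom.sf(k - 1, N, K, n)
                z = norm.isf(max(p, 1e-320))
            else:
                p = hypergeom.cdf(k, N, K, n)
                z = -norm.isf(max(p, 1e-320))
            out.loc[cl, d] = float(np.clip(z, -_Z_CAP, _Z_CAP))
    return out


def srs_retention(
    truth: Mapping,
    selected: Sequence,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-population retention of a downsampled cell selection.

    Columns: population size, cells retained, and whether at least
    ``min_cells`` members survive (the detection criterion).
    """
    sel = set(selected)
    unknown = sel - set(truth)
    if unknown:
        raise ValueError(f"{len(unknown)} selected cells absent from the labeled universe")
    pops = sorted(set(truth.values()))
    rows = []
    for p in pops:
        members = [c for c, lab in truth.items() if lab == p]
        retained = sum(1 for c in members if c in sel)
        rows.append(
            {"population": p, "size": len(members), "retained": retained,
             "detected": retained >= min_cells}
        )
    return pd.DataFrame(rows).set_index("population")


def srs_comparison(
    truth: Mapping,
    sample_size: int,
    min_cells: int = 5,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical SRS baseline: per-population detection rate over random draws
    of ``sample_size`` cells, with the analytic hypergeometric probability."""
    rng = np.random.default_rng(seed)
    cells = sorted(truth)
    N = len(cells)
    pops = sorted(set(truth.values()))
    sizes = {p: sum(1 for c in cells if truth[c] == p) for p in pops}
    detected = {p: 0 for p in pops}
    labels = np.array([truth[c] for c in cells])
    for _ in range(n_draws):
        idx = rng.choice(N, size=sample_size, replace=False)
        drawn = labels[idx]
        for p in pops:
            if (drawn == p).sum() >= min_cells:
                detected[p] += 1
    rows = []
    for p in pops:
        analytic = float(hypergeom.sf(min_cells - 1, N, sizes[p], sample_size))
        rows.append(
            {"population": p, "size": sizes[p],
             "detection_rate": detected[p] / n_draws,
             "analytic_probability": analytic}
        )
    return pd.DataFrame(rows).set_index("population")
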