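"""Synthetic scRNA-seq count matrices with planted cluster structure.

Counts are negative-binomial (over-dispersed Poisson) around gene-specific
base means; each planted cluster up-regulates its own disjoint marker-gene
program by ``marker_fold``. Optional extras emulate the artifacts the
pipeline is designed to handle: doublet-style clusters whose mean profile
is the 50/50 mixture of two parent clusters (hence no unique markers), and
multiplicative donor effects on a random gene subset. Rare populations down
to 0.1% are supported. Everything is driven by a single seed, so fixtures
are bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import ExpressionMatrix, NormState


@dataclass
class FixtureConfig:
    n_cells: int = 1000
    n_genes: int = 2000
    n_clusters: int = 4
    proportions: Optional[Sequence[float]] = None  # default: equal
    markers_per_cluster: int = 50
    marker_fold: float = 8.0
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    base_mean: float = 0.5  # mean counts per gene per cell (typical droplet depth)
    n_doublet_clusters: int = 0
    donor_count: int = 1
    donor_effect_fold: float = 1.0
    donor_gene_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportions is None:
            k = self.n_clusters
            self.proportions = [1.0 / k] * k
        if len(self.proportions) != self.n_clusters:
            raise ValueError("proportions length must equal n_clusters")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.n_clusters + self.n_doublet_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        total_markers = (self.n_clusters + 0) * self.markers_per_cluster
        if total_markers > self.n_genes:
            raise ValueError("marker programs exceed the gene count")


@dataclass
class FixtureData:
    matrix: ExpressionMatrix  # raw counts
    truth: Dict[str, str]  # cell -> planted population label
    donors: Dict[str, str]  # cell -> donor label
    markers: Dict[str, List[str]]  # population -> planted marker genes
    doublet_clusters: List[str]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and var mu + dispersion*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _cluster_sizes(n_cells: int, proportions: Sequence[float]) -> List[int]:
    """Deterministic largest-remainder apportionment of cells to clusters."""
    raw = [p * n_cells for p in proportions]
    sizes = [int(np.floor(x)) for x in raw]
    remainders = sorted(range(len(raw)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in remainders[: n_cells - sum(sizes)]:
        sizes[i] += 1
    return sizes


def generate_dataset(cfg: FixtureConfig) -> FixtureData:
    """Generate a planted-cluster negative-binomial count matrix.

    Marker programs are disjoint across real clusters; doublet clusters mix
    the mean profiles of two parents and contribute no genes of their own.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    # gene-specific baselines: lognormal spread around base_mean
    base = cfg.base_mean * rng.lognormal(mean=0.0, sigma=0.7, size=cfg.n_genes)

    real = [f"pop{k + 1}" for k in range(cfg.n_clusters)]
    markers: Dict[str, List[str]] = {}
    gene_pool = rng.permutation(cfg.n_genes)
    cursor = 0
    mean_profiles: Dict[str, np.ndarray] = {}
    for pop in real:
        idx = gene_pool[cursor : cursor + cfg.markers_per_cluster]
        cursor += cfg.markers_per_cluster
        markers[pop] = sorted(genes[i] for i in idx)
        prof = base.copy()
        prof[idx] *= cfg.marker_fold
        mean_profiles[pop] = prof

    doublets = []
    for d in range(cfg.n_doublet_clusters):
        p1, p2 = real[d % cfg.n_clusters], real[(d + 1) % cfg.n_clusters]
        name = f"doublet_{p1}_{p2}"
        doublets.append(name)
        mean_profiles[name] = 0.5 * (mean_profiles[p1] + mean_profiles[p2])
        markers[name] = []

    pops = real + doublets
    if cfg.n_doublet_clusters:
        # doublet artifacts are rare: each takes 5% of cells off the real clusters
        doublet_frac = 0.05
        props = [p * (1 - doublet_frac * len(doublets)) for p in cfg.proportions]
        props += [doublet_frac] * len(doublets)
    else:
        props = list(cfg.proportions)
    sizes = _cluster_sizes(cfg.n_cells, props)

    labels = np.concatenate([[pops[i]] * s for i, s in enumerate(sizes)])
    rng.shuffle(labels)
    cells = [f"cell{i:05d}" for i in range(cfg.n_cells)]

    donor_ids = [f"donor{d + 1}" for d in range(cfg.donor_count)]
    donor_of = rng.choice(donor_ids, size=cfg.n_cells)
    donor_genes = {
        d: rng.choice(cfg.n_genes, size=int(cfg.donor_gene_fraction * cfg.n_genes), replace=False)
        for d in donor_ids
    }

    counts = np.zeros((cfg.n_genes, cfg.n_cells), dtype=float)
    for j in range(cfg.n_cells):
        mu = mean_profiles[labels[j]].copy()
        if cfg.donor_count > 1 and cfg.donor_effect_fold != 1.0:
            mu[donor_genes[donor_of[j]]] *= cfg.donor_effect_fold
        counts[:, j] = _nb_counts(rng, mu, cfg.nb_dispersion)

    matrix = ExpressionMatrix(genes, cells, counts, NormState.raw_counts)
    return FixtureData(
        matrix=matrix,
        truth=dict(zip(cells, labels)),
        donors=dict(zip(cells, donor_of)),
        markers=markers,
        doublet_clusters=doublets,
    )


def write_fixture(data: FixtureData, outdir: str) -> None:
    """Write a fixture in both supported input formats plus truth tables."""
    import scipy.io
    import scipy.sparse as sp

    from .core_io import write_dense_tsv

    os.makedirs(outdir, exist_ok=True)
    mtx_dir = os.path.join(outdir, "mtx")
    os.makedirs(mtx_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(mtx_dir, "matrix.mtx"), sp.csr_matrix(data.matrix.values))
    with open(os.path.join(mtx_dir, "features.tsv"), "w") as fh:
        for g in data.matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(os.path.join(mtx_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(data.matrix.cell_ids) + "\n")
    write_dense_tsv(data.matrix, os.path.join(outdir, "counts.tsv"), float_format="%g")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("cell\tpopulation\tdonor\n")
        for c in data.matrix.cell_ids:
            fh.write(f"{c}\t{data.truth[c]}\t{data.donors[c]}\n")
    with open(os.path.join(outdir, "markers.tsv"), "w") as fh:
        fh.write("population\tgene\n")
        for pop in sorted(data.markers):
            for g in data.markers[pop]:
                fh.write(f"{pop}\t{g}\n")
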