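"""Expression-matrix input, normalization and gene-class filtering.

Supported inputs are 10x-style MatrixMarket directories (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped), dense tab-delimited
text (genes as rows, first column the gene symbol) and 10x HDF5. Counts are
normalized to CPTT (counts per ten thousand) followed by a log2(1+x)
transform, the scale every downstream stage operates on.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class NormState(str, Enum):
    """Normalization state of an :class:`ExpressionMatrix`."""

    raw_counts = "raw_counts"
    cptt_log2 = "cptt_log2"
    unknown = "unknown"


class MatrixFormatError(ValueError):
    """A required companion file is missing or a cell cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifier bookkeeping.

    Values are stored dense (float64) at desk scale; ``from_sparse`` accepts
    scipy sparse input. Invariants: unique gene and cell identifiers, finite
    non-negative values, dimensions consistent with the identifier lists.
    """

    gene_ids: list
    cell_ids: list
    values: np.ndarray
    norm_state: NormState = NormState.unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("values must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_sparse(cls, gene_ids, cell_ids, matrix, norm_state=NormState.unknown):
        return cls(list(gene_ids), list(cell_ids), np.asarray(matrix.todense(), dtype=float), norm_state)

    def subset_genes(self, genes: Sequence) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.cell_ids), self.values[rows, :], self.norm_state)

    def subset_cells(self, cells: Sequence) -> "ExpressionMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cells]
        return ExpressionMatrix(list(self.gene_ids), list(cells), self.values[:, cols], self.norm_state)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneFilterConfig:
    """Gene-class exclusion switches.

    Mitochondrial, L/S ribosomal and immunoglobulin genes are recognised by
    symbol prefix (overridable with explicit lists); the protein-coding filter
    requires an explicit symbol list and is skipped with a warning when none
    is supplied.
    """

    protein_coding_only: bool = True
    exclude_mito: bool = True
    exclude_ribo_LS: bool = True
    exclude_ig: bool = True
    protein_coding_list: Optional[set] = None
    custom_exclusions: Optional[set] = None

    mito_prefixes: tuple = ("MT-", "mt-")
    ribo_prefixes: tuple = ("RPL", "RPS", "Rpl", "Rps")
    ig_prefixes: tuple = ("IGH", "IGK", "IGL")


def _dedup_symbols(symbols: Iterable[str]) -> list:
    """Disambiguate duplicate symbols by suffixing '.1', '.2', ..."""
    seen: dict = {}
    out = []
    for s in symbols:
        s = str(s)
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _open_maybe_gz(path: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _find_companion(directory: str, stems: Sequence[str]) -> str:
    for stem in stems:
        for ext in ("", ".gz"):
            candidate = os.path.join(directory, stem + ext)
            if os.path.exists(candidate):
                return candidate
    raise MatrixFormatError(
        f"missing companion file in {directory!r}: expected one of {list(stems)}"
    )


def _read_mtx_dir(path: str) -> ExpressionMatrix:
    matrix_path = _find_companion(path, ["matrix.mtx"])
    features_path = _find_companion(path, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_companion(path, ["barcodes.tsv"])
    mat = scipy.io.mmread(matrix_path).tocsr()
    with _open_maybe_gz(features_path) as fh:
        feat = pd.read_csv(fh, sep="\t", header=None)
    # 10x v2/v3: column 1 is the gene symbol when an id column is present
    symbols = feat.iloc[:, 1] if feat.shape[1] >= 2 else feat.iloc[:, 0]
    with _open_maybe_gz(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if mat.shape != (len(symbols), len(barcodes)):
        raise MatrixFormatError(
            f"matrix shape {mat.shape} does not match {len(symbols)} features "
            f"x {len(barcodes)} barcodes"
        )
    return ExpressionMatrix.from_sparse(_dedup_symbols(symbols), barcodes, mat)


def _read_dense_tsv(path: str) -> ExpressionMatrix:
    with _open_maybe_gz(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cells = header[1:]
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise MatrixFormatError(f"non-numeric value at line {lineno}: {exc}") from exc
            if len(parts) - 1 != len(cells):
                raise MatrixFormatError(
                    f"line {lineno} has {len(parts) - 1} values, expected {len(cells)}"
                )
    return ExpressionMatrix(_dedup_symbols(genes), cells, np.array(rows, dtype=float))


def _read_10x_h5(path: str) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        if "matrix" in f:  # 10x v3 schema
            grp = f["matrix"]
            symbols = [s.decode() for s in grp["features/name"][:]]
        else:  # v2: one genome group
            grp = f[list(f.keys())[0]]
            symbols = [s.decode() for s in grp["gene_names"][:]]
        barcodes = [b.decode() for b in grp["barcodes"][:]]
        mat = sp.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=tuple(grp["shape"][:]),
        )
    return ExpressionMatrix.from_sparse(_dedup_symbols(symbols), barcodes, mat)


def read_matrix(path: str, format: str = "dense_tsv") -> ExpressionMatrix:
    """Read an expression matrix; ``format`` is one of mtx_dir/dense_tsv/h5.

    The normalization state is flagged ``raw_counts`` when every value is an
    integer, otherwise ``unknown``.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    readers = {"mtx_dir": _read_mtx_dir, "dense_tsv": _read_dense_tsv, "h5": _read_10x_h5}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    m = readers[format](path)
    integral = np.all(m.values == np.round(m.values))
    m.norm_state = NormState.raw_counts if integral else NormState.unknown
    return m


def write_dense_tsv(m: ExpressionMatrix, path: str, float_format: Optional[str] = None) -> None:
    """Write as dense TSV with 'Gene' as the first header field."""
    df = m.to_frame()
    df.index.name = "Gene"
    df.to_csv(path, sep="\t", float_format=float_format)


def normalize_cptt(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-ten-thousand normalization with a log2(1+x) transform.

    value' = log2(1 + 10000 * value / column_total). Cells with zero total
    counts are dropped with a warning. A second call is a no-op.
    """
    if m.norm_state == NormState.cptt_log2:
        warnings.warn("matrix already CPTT/log2 normalized; returning unchanged")
        return m
    totals = m.values.sum(axis=0)
    keep = totals > 0
    if not np.all(keep):
        dropped = [c for c, k in zip(m.cell_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} all-zero cells: {dropped[:10]}")
    vals = m.values[:, keep]
    cptt = vals * (10000.0 / totals[keep])
    out = np.log2(1.0 + cptt)
    return ExpressionMatrix(
        list(m.gene_ids),
        [c for c, k in zip(m.cell_ids, keep) if k],
        out,
        NormState.cptt_log2,
    )


def delog_cptt(values: np.ndarray) -> np.ndarray:
    """Invert the log2(1+x) transform back to the CPTT scale."""
    return np.exp2(values) - 1.0


def gene_class_mask(gene_ids: Sequence[str], cfg: GeneFilterConfig) -> np.ndarray:
    """Boolean mask of genes to KEEP under the class-exclusion rules."""
    keep = np.ones(len(gene_ids), dtype=bool)
    for i, g in enumerate(gene_ids):
        base = g.split(".")[0] if g[-1:].isdigit() and "." in g else g
        if cfg.exclude_mito and g.startswith(cfg.mito_prefixes):
            keep[i] = False
        elif cfg.exclude_ribo_LS and g.startswith(cfg.ribo_prefixes):
            keep[i] = False
        elif cfg.exclude_ig and g.startswith(cfg.ig_prefixes):
            keep[i] = False
        elif cfg.custom_exclusions and (g in cfg.custom_exclusions or base in cfg.custom_exclusions):
            keep[i] = False
    if cfg.protein_coding_only:
        if not cfg.protein_coding_list:
            warnings.warn(
                "protein_coding_only requested but no protein_coding_list supplied; "
                "skipping the protein-coding filter"
            )
        else:
            pc = cfg.protein_coding_list
            for i, g in enumerate(gene_ids):
                base = g.split(".")[0] if "." in g else g
                if g not in pc and base not in pc:
                    keep[i] = False
    return keep


def apply_gene_filters(m: ExpressionMatrix, cfg: Optional[GeneFilterConfig] = None) -> ExpressionMatrix:
    """Remove excluded gene classes; cell set and gene order are preserved."""
    cfg = cfg or GeneFilterConfig()
    keep = gene_class_mask(m.gene_ids, cfg)
    if not keep.any():
        raise ValueError(
            "gene-class filtering removed every gene; relax the filters "
            "(e.g. disable protein_coding_only or supply a larger list)"
        )
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(m.cell_ids), m.values[keep, :], m.norm_state)
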