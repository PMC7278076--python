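"""Read and write 10x Genomics-style sparse UMI count matrices.

The on-disk layout is the standard triplet directory: a MatrixMarket
coordinate file (``matrix.mtx``) with 1-based indices, a ``barcodes.tsv``
with one barcode per line, and either a 3-column ``features.tsv``
(id, symbol, type) or a legacy 2-column ``genes.tsv`` (id, symbol).
All three may be gzipped. Indices are converted to 0-based in memory.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "read_10x_mtx",
    "write_10x_mtx",
    "drop_empty",
    "barcode_totals",
]


@dataclass
class CountMatrix:
    """A genes-by-barcodes sparse matrix of non-negative integer UMI counts.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    barcode_ids
        Unique barcode identifiers, one per matrix column.
    counts
        Sparse ``(n_genes, n_barcodes)`` matrix; stored as CSC int64.
    gene_symbols
        Optional human-readable gene symbols (may contain duplicates as
        long as ``gene_ids`` are unique).
    """

    gene_ids: list
    barcode_ids: list
    counts: sp.spmatrix
    gene_symbols: list | None = field(default=None)

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcode_ids = [str(b) for b in self.barcode_ids]
        mat = sp.csc_matrix(self.counts)
        if mat.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcode_ids)} barcodes"
            )
        if mat.nnz:
            data = mat.data
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValueError("counts must be integers")
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
        mat = mat.astype(np.int64)
        mat.eliminate_zeros()
        self.counts = mat
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise ValueError("barcode_ids are not unique")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.gene_ids):
            raise ValueError("gene_symbols length mismatch")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self):
        return self.counts.shape

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.barcode_ids == other.barcode_ids
            and self.shape == other.shape
            and (self.counts != other.counts).nnz == 0
        )


def _find(base: Path, stems) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = base / name
            if p.is_file():
                return p
    raise FileNotFoundError(f"none of {stems} found in {base}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path):
    with _open_text(path) as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_10x_mtx(path) -> CountMatrix:
    """Load a 10x triplet directory (plain or gzipped) as a CountMatrix."""
    base = Path(path)
    if not base.is_dir():
        raise FileNotFoundError(f"{base} is not a directory")
    mtx_path = _find(base, ["matrix.mtx"])
    bc_path = _find(base, ["barcodes.tsv"])
    feat_path = _find(base, ["features.tsv", "genes.tsv"])

    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(str(mtx_path))
    mat = sp.coo_matrix(mat)
    if mat.nnz:
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError("matrix contains non-integer values")
        if mat.data.min() < 0:
            raise ValueError("matrix contains negative values")

    barcodes = [line.split("\t")[0] for line in _read_lines(bc_path)]
    feat_rows = [line.split("\t") for line in _read_lines(feat_path)]
    gene_ids = [row[0] for row in feat_rows]
    gene_symbols = [row[1] if len(row) > 1 else row[0] for row in feat_rows]

    if len(gene_ids) != mat.shape[0]:
        raise ValueError(
            f"feature file has {len(gene_ids)} entries but matrix declares {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"barcode file has {len(barcodes)} entries but matrix declares {mat.shape[1]} columns"
        )
    return CountMatrix(gene_ids, barcodes, mat, gene_symbols=gene_symbols)


def write_10x_mtx(m: CountMatrix, path) -> None:
    """Write a CountMatrix as an uncompressed 10x triplet directory."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(base / "matrix.mtx"), sp.coo_matrix(m.counts), field="integer")
    with open(base / "barcodes.tsv", "w") as fh:
        for bc in m.barcode_ids:
            fh.write(bc + "\n")
    symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    with open(base / "features.tsv", "w") as fh:
        for gid, sym in zip(m.gene_ids, symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")


def barcode_totals(m: CountMatrix) -> np.ndarray:
    """Per-barcode total UMI counts (column sums)."""
    return np.asarray(m.counts.sum(axis=0)).ravel().astype(np.int64)


def drop_empty(m: CountMatrix) -> CountMatrix:
    """Remove all-zero gene rows and all-zero barcode columns.

    Raises ``ValueError`` if the matrix has no counts at all.
    """
    col = np.asarray(m.counts.sum(axis=0)).ravel()
    row = np.asarray(m.counts.sum(axis=1)).ravel()
    if col.sum() == 0:
        raise ValueError("matrix is entirely zero; nothing to analyze")
    keep_r = row > 0
    keep_c = col > 0
    if keep_r.all() and keep_c.all():
        return m
    sub = m.counts[np.ix_(np.flatnonzero(keep_r), np.flatnonzero(keep_c))]
    syms = None
    if m.gene_symbols is not None:
        syms = [s for s, k in zip(m.gene_symbols, keep_r) if k]
    return CountMatrix(
        [g for g, k in zip(m.gene_ids, keep_r) if k],
        [b for b, k in zip(m.barcode_ids, keep_c) if k],
        sub,
        gene_symbols=syms,
    )
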