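"""Core data model: sparse UMI count matrices, per-cell annotations, QC, normalization.

The container is gene-by-cell (features as rows), matching the MatrixMarket
triplet convention used by droplet-based single-cell pipelines.  Two
normalization transforms are provided: ``log2(count + 1)`` and a per-gene
z-score of those log values; every downstream scoring step consumes one of
the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

TISSUES = ("tumor", "adjacent")

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "QcReport",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_cell_meta",
    "attach_metadata",
    "qc_filter",
    "normalize_log2",
    "zscore_by_gene",
]


class ImmscapeError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class ExpressionMatrix:
    """Sparse non-negative integer UMI counts, genes x cells.

    Parameters
    ----------
    counts
        CSR matrix of shape ``(n_genes, n_cells)`` holding raw UMI counts.
    gene_ids
        Unique gene symbols, one per matrix row.
    cell_barcodes
        Unique cell barcodes, one per matrix column.
    cell_meta
        Optional per-cell annotation frame indexed by barcode.  Required
        columns once attached: ``patient_id`` and ``tissue`` (one of
        ``tumor`` / ``adjacent``); ``cell_type`` and ``cluster`` are used by
        downstream stages when present.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_barcodes = pd.Index(self.cell_barcodes)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ImmscapeError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} barcodes"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ImmscapeError(f"duplicate gene id(s): {dups[:5]}")
        if self.cell_barcodes.has_duplicates:
            dups = self.cell_barcodes[self.cell_barcodes.duplicated()].unique().tolist()
            raise ImmscapeError(f"duplicate barcode(s): {dups[:5]}")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ImmscapeError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise ImmscapeError("non-integer count entry")
        if self.cell_meta is not None:
            self._validate_meta(self.cell_meta)

    def _validate_meta(self, meta: pd.DataFrame) -> None:
        missing = self.cell_barcodes.difference(meta.index)
        if len(missing):
            raise ImmscapeError(
                f"{len(missing)} cell(s) missing from metadata, e.g. "
                f"{missing[:5].tolist()}"
            )
        for col in ("patient_id", "tissue"):
            if col not in meta.columns:
                raise ImmscapeError(f"metadata lacks required column '{col}'")
        bad = set(meta["tissue"].unique()) - set(TISSUES)
        if bad:
            raise ImmscapeError(f"unknown tissue value(s) {sorted(bad)}; expected {TISSUES}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        meta = self.cell_meta.loc[self.cell_barcodes[mask]] if self.cell_meta is not None else None
        return ExpressionMatrix(
            counts=self.counts[:, mask].tocsr(),
            gene_ids=self.gene_ids,
            cell_barcodes=self.cell_barcodes[mask],
            cell_meta=meta,
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata

        obs = (
            self.cell_meta.loc[self.cell_barcodes].copy()
            if self.cell_meta is not None
            else pd.DataFrame(index=self.cell_barcodes)
        )
        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=obs,
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class NormalizedMatrix:
    """Real-valued genes x cells matrix on a declared scale.

    ``scale`` is either ``"log2p1"`` (``log2(count + 1)``, all values >= 0)
    or ``"zscore_log2p1"`` (per-gene z-score of the log values; constant
    genes map to all-zero rows).
    """

    values: Union[sp.csr_matrix, np.ndarray]
    scale: str
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    cell_meta: Optional[pd.DataFrame] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("log2p1", "zscore_log2p1"):
            raise ImmscapeError(f"unknown scale '{self.scale}'")
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_barcodes = pd.Index(self.cell_barcodes)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense 1-D values of one gene across all cells."""
        if gene not in self.gene_ids:
            raise KeyError(f"gene '{gene}' not in matrix")
        i = self.gene_ids.get_loc(gene)
        row = self.values[i]
        if sp.issparse(row):
            return np.asarray(row.todense()).ravel()
        return np.asarray(row).ravel()

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class QcReport:
    """Accounting of a cell-level quality filter.

    A cell failing both rules is tallied once, under ``n_removed_low_genes``,
    so that ``n_cells_kept + n_removed_low_genes + n_removed_high_mito ==
    n_cells_in``.
    """

    n_cells_in: int
    n_cells_kept: int
    n_removed_low_genes: int
    n_removed_high_mito: int
    min_genes: int
    max_mito_frac: float
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        total = self.n_cells_kept + self.n_removed_low_genes + self.n_removed_high_mito
        if total != self.n_cells_in:
            raise ImmscapeError("QC report counts do not add up")


# ---------------------------------------------------------------------------
# readers / writers


def _read_sidecar(path: Union[str, Path], what: str) -> pd.Index:
    """Read a one-record-per-line sidecar (features or barcodes).

    Features files may carry extra columns (id / symbol / type); the symbol
    column (second) is used when present, else the first.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    col = 1 if (what == "feature" and df.shape[1] >= 2) else 0
    idx = pd.Index(df.iloc[:, col].astype(str))
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ImmscapeError(f"duplicate {what}: {dups[:5]}")
    return idx


def read_counts_mtx(
    matrix_path: Union[str, Path],
    features_path: Union[str, Path],
    barcodes_path: Union[str, Path],
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet count file with its two sidecar tables.

    Genes are rows, cells are columns (the 10x triplet dialect).  Entries
    must be non-negative integers; absent triplets are zeros.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = _read_sidecar(features_path, "feature")
    barcodes = _read_sidecar(barcodes_path, "barcode")
    if mat.shape != (len(genes), len(barcodes)):
        raise ImmscapeError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(barcodes)} barcodes)"
        )
    return ExpressionMatrix(
        counts=sp.csr_matrix(mat), gene_ids=genes, cell_barcodes=barcodes
    )


def write_counts_mtx(matrix: ExpressionMatrix, outdir: Union[str, Path],
                     prefix: str = "") -> dict:
    """Write matrix.mtx + features.tsv + barcodes.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.counts), field="integer")
    paths["features"].write_text("\n".join(matrix.gene_ids) + "\n")
    paths["barcodes"].write_text("\n".join(matrix.cell_barcodes) + "\n")
    return paths


def read_cell_meta(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-cell annotation table (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if "barcode" not in meta.columns:
        raise ImmscapeError("annotation table lacks a 'barcode' column")
    return meta.set_index("barcode")


def attach_metadata(
    matrix: ExpressionMatrix, meta: Union[pd.DataFrame, str, Path]
) -> ExpressionMatrix:
    """Attach per-cell annotations, validating coverage and tissue labels.

    Every barcode in the matrix must appear in ``meta``; extra annotation
    rows are ignored with a warning (they may describe cells removed by QC
    upstream).
    """
    if not isinstance(meta, pd.DataFrame):
        meta = read_cell_meta(meta)
    extra = meta.index.difference(matrix.cell_barcodes)
    if len(extra):
        warnings.warn(f"{len(extra)} annotation row(s) have no matching cell; ignored")
    out = ExpressionMatrix(
        counts=matrix.counts,
        gene_ids=matrix.gene_ids,
        cell_barcodes=matrix.cell_barcodes,
        cell_meta=meta.loc[meta.index.intersection(matrix.cell_barcodes)],
    )
    return out


# ---------------------------------------------------------------------------
# QC and normalization


def cell_qc_metrics(matrix: ExpressionMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell detected-gene counts, total counts, and mitochondrial fraction."""
    csc = matrix.counts.tocsc()
    detected = np.diff(csc.indptr)  # nonzero entries per column
    total = np.asarray(csc.sum(axis=0)).ravel()
    is_mito = np.asarray(matrix.gene_ids.str.startswith(mito_prefix))
    mito_counts = np.asarray(csc[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"detected_genes": detected, "total_counts": total, "mito_frac": mito_frac},
        index=matrix.cell_barcodes,
    )


def qc_filter(
    matrix: ExpressionMatrix,
    min_genes: int = 400,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, QcReport]:
    """Remove low-quality cells: fewer than ``min_genes`` detected genes, or a
    mitochondrial count fraction above ``max_mito_frac``.

    Both bounds are inclusive for keeping: a cell with exactly ``min_genes``
    detected genes or a mitochondrial fraction exactly at the threshold is
    retained.  Mitochondrial genes are identified by id prefix (default
    ``MT-``); the fraction is mitochondrial counts over total counts.
    """
    metrics = cell_qc_metrics(matrix, mito_prefix=mito_prefix)
    low_genes = (metrics["detected_genes"] < min_genes).to_numpy()
    high_mito = (metrics["mito_frac"] > max_mito_frac).to_numpy()
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ImmscapeError("empty matrix after QC")
    report = QcReport(
        n_cells_in=matrix.n_cells,
        n_cells_kept=int(keep.sum()),
        n_removed_low_genes=int(low_genes.sum()),
        n_removed_high_mito=int((high_mito & ~low_genes).sum()),
        min_genes=min_genes,
        max_mito_frac=max_mito_frac,
        mito_prefix=mito_prefix,
    )
    return matrix.subset_cells(keep), report


def normalize_log2(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """``log2(count + 1)`` transform; zeros stay zero so sparsity is kept."""
    values = matrix.counts.astype(np.float64).copy()
    values.data = np.log2(values.data + 1.0)
    return NormalizedMatrix(
        values=values,
        scale="log2p1",
        gene_ids=matrix.gene_ids,
        cell_barcodes=matrix.cell_barcodes,
        cell_meta=matrix.cell_meta,
        provenance="log2p1(counts)",
    )


def zscore_by_gene(
    norm: NormalizedMatrix, within: Optional[Sequence] = None
) -> NormalizedMatrix:
    """Per-gene z-score of log values, optionally over a cell subset.

    Uses the population standard deviation (divide by n).  Genes constant
    over the chosen cells map to all-zero rows.  ``within`` may be a boolean
    mask or a list of barcodes; when given, only those cells appear in the
    result.
    """
    if norm.scale != "log2p1":
        raise ImmscapeError("zscore_by_gene expects a log2p1-scale matrix")
    if within is None:
        cols = np.arange(norm.values.shape[1])
    else:
        within = np.asarray(within)
        if within.dtype == bool:
            cols = np.flatnonzero(within)
        else:
            cols = norm.cell_barcodes.get_indexer(pd.Index(within))
            if (cols < 0).any():
                raise ImmscapeError("subset barcode not found in matrix")
    if len(cols) == 0:
        raise ImmscapeError("empty cell subset")
    dense = norm.values[:, cols]
    if sp.issparse(dense):
        dense = np.asarray(dense.todense())
    else:
        dense = np.asarray(dense, dtype=np.float64).copy()
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)  # population convention
    out = np.where(sd > 0, (dense - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    barcodes = norm.cell_barcodes[cols]
    meta = norm.cell_meta.loc[barcodes] if norm.cell_meta is not None else None
    return NormalizedMatrix(
        values=out,
        scale="zscore_log2p1",
        gene_ids=norm.gene_ids,
        cell_barcodes=barcodes,
        cell_meta=meta,
        provenance=norm.provenance + " -> zscore_by_gene",
    )
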