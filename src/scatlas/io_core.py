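"""Expression-matrix I/O, QC filtering, and normalization layers.

The central data container is :class:`ExpressionMatrix`, which carries up to
three cell-by-gene layers:

``raw``
    non-negative integer UMI counts (sparse CSR),
``lognorm``
    ``log2(1 + count / cell_total * scale)`` with ``scale`` defaulting to
    one million (a TPM-like per-cell normalization),
``centered``
    per-gene mean-centered ``lognorm`` with magnitudes capped (no variance
    scaling).

Cell-level QC (mitochondrial fraction, UMI and detected-gene ranges) and
gene-level prevalence filtering are applied to the raw layer; downstream
modules consume ``lognorm`` and ``centered``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from scatlas._errors import FormatError, ValidationError

TISSUE_ORIGINS = ("nLung", "tLung", "tL/B", "nLN", "mLN", "PE", "mBrain")

METADATA_COLUMNS = ("cell_id", "sample_id", "tissue_origin", "lineage", "subset")


@dataclass
class QcThresholds:
    """Cell- and gene-level QC cutoffs (all bounds inclusive)."""

    max_mito_fraction: float = 0.20
    umi_range: tuple[int, int] = (100, 150_000)
    gene_range: tuple[int, int] = (200, 10_000)
    min_gene_cell_fraction: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")
        if not 0.0 <= self.min_gene_cell_fraction <= 1.0:
            raise ValidationError("min_gene_cell_fraction must be in [0, 1]")
        if self.umi_range[0] > self.umi_range[1]:
            raise ValidationError("umi_range is not ordered")
        if self.gene_range[0] > self.gene_range[1]:
            raise ValidationError("gene_range is not ordered")


class ExpressionMatrix:
    """Cells-by-genes expression with raw, log-normalized and centered layers.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique identifiers for the rows (cells) and columns (genes).
    raw
        Non-negative integer UMI counts, any scipy-sparse or dense type.
    """

    def __init__(
        self,
        cell_ids: Sequence[str],
        gene_ids: Sequence[str],
        raw,
        lognorm=None,
        centered: np.ndarray | None = None,
    ) -> None:
        self.cell_ids = list(map(str, cell_ids))
        self.gene_ids = list(map(str, gene_ids))
        self.raw = sp.csr_matrix(raw)
        self.lognorm = None if lognorm is None else sp.csr_matrix(lognorm)
        self.centered = None if centered is None else np.asarray(centered, dtype=float)
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        n_cells, n_genes = self.raw.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix shape {self.raw.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if self.raw.nnz:
            data = self.raw.data
            if data.min() < 0:
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("raw counts must be integral")
        for layer in (self.lognorm, self.centered):
            if layer is not None and layer.shape != self.raw.shape:
                raise FormatError("layer shapes inconsistent with raw")

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise ValidationError(f"cells not in matrix: {missing}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            [self.cell_ids[i] for i in index],
            self.gene_ids,
            self.raw[index],
            None if self.lognorm is None else self.lognorm[index],
            None if self.centered is None else self.centered[index],
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            self.cell_ids,
            [self.gene_ids[i] for i in index],
            self.raw[:, index],
            None if self.lognorm is None else self.lognorm[:, index],
            None if self.centered is None else self.centered[:, index],
        )

    def lognorm_dense(self) -> np.ndarray:
        if self.lognorm is None:
            raise ValidationError("lognorm layer not computed; run normalize_log2_tpm")
        return np.asarray(self.lognorm.todense(), dtype=float)


@dataclass
class CellAnnotation:
    """Per-cell sample, tissue-origin, lineage and subset labels."""

    table: pd.DataFrame
    origin_vocabulary: tuple[str, ...] = TISSUE_ORIGINS

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["cell_id"].astype(str)
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids in metadata: {dups[:5]}")
        bad = set(self.table["tissue_origin"]) - set(self.origin_vocabulary)
        if bad:
            raise ValidationError(
                f"tissue_origin values outside {self.origin_vocabulary}: {sorted(bad)}"
            )
        if (self.table["lineage"].astype(str).str.len() == 0).any():
            raise ValidationError("empty lineage labels")

    @classmethod
    def read_tsv(cls, path: str | Path, **kwargs) -> "CellAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str), **kwargs)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        order = {c: i for i, c in enumerate(cell_ids)}
        sub = self.table[self.table["cell_id"].isin(order)].copy()
        sub = sub.sort_values("cell_id", key=lambda s: s.map(order))
        return CellAnnotation(sub, self.origin_vocabulary)

    def cells_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for column, value in conditions.items():
            if isinstance(value, (set, frozenset, list, tuple)):
                mask &= self.table[column].isin(value)
            else:
                mask &= self.table[column] == value
        return self.table.loc[mask, "cell_id"].tolist()


@dataclass
class GeneAnnotation:
    """Gene chromosome and 1-based start position."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "chromosome", "start") if c not in self.table.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["start"] = self.table["start"].astype(int)
        if (self.table["start"] < 1).any():
            raise ValidationError("gene start positions must be >= 1")
        if self.table["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def positions_for(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        indexed = self.table.set_index("gene_id")
        missing = [g for g in gene_ids if g not in indexed.index]
        if missing:
            raise ValidationError(f"genes missing chromosome/start annotation: {missing[:10]}")
        return indexed.loc[list(gene_ids), ["chromosome", "start"]]


# -- loading ------------------------------------------------------------------------


def _read_single_column(path: Path) -> list[str]:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].tolist()


def _load_mtx_triplet(directory: Path) -> tuple[list[str], list[str], sp.csr_matrix]:
    matrix_path = directory / "matrix.mtx"
    barcodes_path = directory / "barcodes.tsv"
    features_path = directory / "features.tsv"
    if not features_path.exists() and (directory / "genes.tsv").exists():
        features_path = directory / "genes.tsv"
    for p in (matrix_path, barcodes_path, features_path):
        if not p.exists():
            raise FormatError(f"missing {p.name} in {directory}")
    barcodes = _read_single_column(barcodes_path)
    features = _read_single_column(features_path)
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    # 10x convention stores features x barcodes; accept either orientation.
    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T.tocsr()
    elif mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(features)} features x {len(barcodes)} barcodes nor its transpose"
        )
    return barcodes, features, mat


def _load_dense_tsv(path: Path, known_cells: set[str]) -> tuple[list[str], list[str], sp.csr_matrix]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    rows = list(map(str, frame.index))
    cols = list(map(str, frame.columns))
    row_hits = sum(r in known_cells for r in rows)
    col_hits = sum(c in known_cells for c in cols)
    if col_hits > row_hits:  # genes x cells: transpose to cell-major
        frame = frame.T
        rows, cols = cols, rows
    return rows, cols, sp.csr_matrix(frame.to_numpy())


def load_counts(
    path: str | Path, metadata_path: str | Path
) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Load UMI counts (MTX triplet directory or dense TSV) plus cell metadata.

    Every barcode in the matrix must be covered by the metadata; missing
    barcodes raise :class:`ValidationError` naming them.
    """
    path = Path(path)
    annotation = CellAnnotation.read_tsv(metadata_path)
    known = set(annotation.table["cell_id"])
    if path.is_dir():
        barcodes, genes, mat = _load_mtx_triplet(path)
    else:
        barcodes, genes, mat = _load_dense_tsv(path, known)
    missing = [b for b in barcodes if b not in known]
    if missing:
        raise ValidationError(f"metadata missing for barcodes: {missing[:10]}")
    matrix = ExpressionMatrix(barcodes, genes, mat)
    return matrix, annotation.subset(barcodes)


# -- QC and normalization -----------------------------------------------------------


def default_mito_genes(gene_ids: Iterable[str]) -> set[str]:
    """Mitochondrial genes by the conventional ``MT-`` symbol prefix."""
    return {g for g in gene_ids if g.upper().startswith("MT-")}


def qc_filter_cells(
    matrix: ExpressionMatrix,
    mito_genes: set[str] | None = None,
    thresholds: QcThresholds | None = None,
) -> ExpressionMatrix:
    """Retain cells passing mitochondrial-fraction, UMI and gene-count gates.

    A cell survives iff ``mito_fraction <= max_mito_fraction`` and its total
    UMI and detected-gene counts fall inside the (inclusive) configured
    ranges. Cell order is preserved.
    """
    thresholds = thresholds or QcThresholds()
    if mito_genes is None:
        mito_genes = default_mito_genes(matrix.gene_ids)
    unknown = mito_genes - set(matrix.gene_ids)
    if unknown:
        raise ValidationError(f"mito genes absent from matrix: {sorted(unknown)[:10]}")

    totals = np.asarray(matrix.raw.sum(axis=1)).ravel()
    genes_detected = np.asarray((matrix.raw > 0).sum(axis=1)).ravel()
    if mito_genes:
        idx = matrix.gene_index(sorted(mito_genes))
        mito_totals = np.asarray(matrix.raw[:, idx].sum(axis=1)).ravel()
    else:
        mito_totals = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    keep = (
        (mito_fraction <= thresholds.max_mito_fraction)
        & (totals >= thresholds.umi_range[0])
        & (totals <= thresholds.umi_range[1])
        & (genes_detected >= thresholds.gene_range[0])
        & (genes_detected <= thresholds.gene_range[1])
    )
    if not keep.any():
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return matrix.subset_cells(keep)


def min_cells_required(min_cell_fraction: float, n_cells: int) -> int:
    """Smallest expressing-cell count retained: ceil(fraction x cells)."""
    return int(math.ceil(min_cell_fraction * n_cells - 1e-9))


def filter_genes(matrix: ExpressionMatrix, min_cell_fraction: float = 0.001) -> ExpressionMatrix:
    """Drop genes expressed in fewer than ``ceil(fraction x n_cells)`` cells."""
    required = min_cells_required(min_cell_fraction, matrix.n_cells)
    expressing = np.asarray((matrix.raw > 0).sum(axis=0)).ravel()
    keep = expressing >= max(required, 1)
    if not keep.any():
        warnings.warn("all genes removed by prevalence filter", stacklevel=2)
    return matrix.subset_genes(keep)


def normalize_log2_tpm(matrix: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Populate ``lognorm = log2(1 + count / cell_total * scale)``.

    Zeros stay exactly zero, so the layer keeps the raw sparsity pattern.
    """
    totals = np.asarray(matrix.raw.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValidationError(
            f"cells with zero total UMI (run qc_filter_cells first): {bad}"
        )
    lognorm = matrix.raw.tocoo().astype(float)
    lognorm.data = np.log2(1.0 + lognorm.data / totals[lognorm.row] * scale)
    matrix.lognorm = lognorm.tocsr()
    return matrix


def center_relative(matrix: ExpressionMatrix, cap: float = 10.0) -> ExpressionMatrix:
    """Populate ``centered``: per-gene mean-centered lognorm clipped to ±cap.

    No variance scaling is applied.
    """
    dense = matrix.lognorm_dense()
    centered = dense - dense.mean(axis=0, keepdims=True)
    matrix.centered = np.clip(centered, -cap, cap)
    return matrix


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the raw layer as a dense cells x genes TSV (cell_id index)."""
    frame = pd.DataFrame(
        np.asarray(matrix.raw.todense(), dtype=int),
        index=pd.Index(matrix.cell_ids, name="cell_id"),
        columns=matrix.gene_ids,
    )
    frame.to_csv(path, sep="\t")
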