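"""Reading, QC filtering, normalization and namespace harmonization of
single-cell expression matrices.

The in-memory container is :class:`ExpressionMatrix`, a gene-by-cell dense
matrix with gene identifiers and a per-cell metadata table.  Matrices are
read either from the 10x Genomics sparse-triplet convention
(``matrix.mtx[.gz]`` + ``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``) or from
a dense TSV/CSV with gene rows and cell columns.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .genesets import GeneUniverse

logger = logging.getLogger(__name__)

CPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Gene-by-cell expression matrix with identifiers and cell metadata.

    Parameters
    ----------
    values
        Non-negative ``(n_genes, n_cells)`` array of raw counts or CPM.
    gene_ids
        Unique gene identifiers, one per row.
    cell_meta
        Per-cell table indexed like the columns of ``values``.  Recognised
        optional columns: ``cell_type``, ``dataset``, ``is_doublet``.
    normalized
        Either ``"counts"`` or ``"cpm"``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    normalized: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene-by-cell matrix")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique (see deduplicate_genes)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.normalized not in ("counts", "cpm"):
            raise ValueError("normalized must be 'counts' or 'cpm'")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.RangeIndex(self.n_cells))
        if len(self.cell_meta) != self.n_cells:
            raise ValueError("cell_meta length does not match cell dimension")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[:, mask],
            self.gene_ids.copy(),
            self.cell_meta.loc[np.asarray(mask)].copy(),
            self.normalized,
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_table_column(path: str | Path, column: int = 0) -> list[str]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[column])
    return out


def _deduplicate_genes(values: np.ndarray, gene_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve duplicated gene ids by keeping the row with the larger total."""
    ids = pd.Index(gene_ids)
    if ids.is_unique:
        return values, gene_ids
    totals = values.sum(axis=1)
    keep = np.zeros(len(gene_ids), dtype=bool)
    order = pd.DataFrame({"gene": gene_ids, "total": totals})
    # stable: on equal totals the earlier row wins
    best = order.sort_values("total", kind="stable").groupby("gene").tail(1).index
    keep[best] = True
    n_dropped = (~keep).sum()
    logger.info("deduplicated %d duplicate gene rows (kept larger totals)", n_dropped)
    keep_idx = np.flatnonzero(keep)
    return values[keep_idx], gene_ids[keep_idx]


def read_sparse_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    cell_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a 10x-convention sparse triplet (MatrixMarket + sidecar tables).

    The matrix is genes-by-cells.  Duplicate gene identifiers are resolved by
    keeping the row with the larger total count.  A dimension mismatch between
    the matrix and either sidecar file is a hard error naming the file.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = scipy.sparse.coo_matrix(mat).toarray().astype(np.float64)
    genes = _read_table_column(features_path, 0)
    barcodes = _read_table_column(barcodes_path, 0)
    if len(genes) != mat.shape[0]:
        raise ValueError(
            f"features file {features_path} has {len(genes)} rows but the "
            f"matrix declares {mat.shape[0]} genes"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"barcodes file {barcodes_path} has {len(barcodes)} rows but the "
            f"matrix declares {mat.shape[1]} cells"
        )
    values, gene_ids = _deduplicate_genes(mat, np.asarray(genes, dtype=object))
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    else:
        cell_meta = cell_meta.reindex(barcodes)
    return ExpressionMatrix(values, gene_ids, cell_meta)


def read_dense(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a dense gene-by-cell table (first column gene ids, header cells)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression table: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression table: {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric value at gene {df.index[bad[0]]!r}, "
            f"cell {df.columns[bad[1]]!r} in {path}"
        )
    values, gene_ids = _deduplicate_genes(
        numeric.to_numpy(dtype=np.float64), df.index.to_numpy(dtype=object)
    )
    meta = pd.DataFrame(index=pd.Index(df.columns, name="barcode"))
    return ExpressionMatrix(values, gene_ids, meta)


def qc_filter(
    em: ExpressionMatrix,
    mito_prefix: str = "MT-",
    mito_max: float = 0.5,
    min_genes: int = 200,
    max_genes: int = 6000,
) -> ExpressionMatrix:
    """Remove doublet-flagged cells, then apply mitochondrial and gene-count QC.

    Cells are kept when their mitochondrial read fraction is strictly below
    ``mito_max`` and their number of detected genes lies in the inclusive
    interval ``[min_genes, max_genes]``.  Mitochondrial genes are recognised
    by identifier prefix.  Operates on raw counts.
    """
    keep = np.ones(em.n_cells, dtype=bool)
    if "is_doublet" in em.cell_meta.columns:
        keep &= ~em.cell_meta["is_doublet"].fillna(False).to_numpy(dtype=bool)

    totals = em.values.sum(axis=0)
    mito_rows = np.array([str(g).startswith(mito_prefix) for g in em.gene_ids])
    mito_counts = em.values[mito_rows].sum(axis=0) if mito_rows.any() else np.zeros(em.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    detected = (em.values > 0).sum(axis=0)

    keep &= mito_frac < mito_max
    keep &= (detected >= min_genes) & (detected <= max_genes)
    if not keep.any():
        raise ValueError(
            "no cells pass QC; review mito_max/min_genes/max_genes thresholds"
        )
    return em.subset_cells(keep)


def cpm_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to a total of one million (CPM). All-zero cells stay zero."""
    if em.normalized == "cpm":
        logger.warning("matrix already CPM normalized; returning unchanged")
        return em
    totals = em.values.sum(axis=0)
    scale = np.where(totals > 0, CPM_TOTAL / np.where(totals > 0, totals, 1.0), 0.0)
    return ExpressionMatrix(
        em.values * scale, em.gene_ids.copy(), em.cell_meta.copy(), "cpm"
    )


def harmonize_universe(em: ExpressionMatrix, universe: GeneUniverse) -> ExpressionMatrix:
    """Fit the matrix to a fixed gene universe.

    The output gene axis is exactly ``universe.genes`` in universe order:
    universe genes missing from the dataset become all-zero rows; dataset
    genes absent from the universe are dropped.
    """
    uni = list(universe.genes)
    pos = {g: i for i, g in enumerate(em.gene_ids)}
    shared = [g for g in uni if g in pos]
    if not shared:
        raise ValueError(
            "no overlap between dataset genes and the universe; "
            "likely a gene-namespace mismatch"
        )
    n_dropped = em.n_genes - len(shared)
    if n_dropped:
        logger.info("dropped %d genes absent from the universe", n_dropped)
    out = np.zeros((len(uni), em.n_cells), dtype=np.float64)
    idx_in_uni = [i for i, g in enumerate(uni) if g in pos]
    idx_in_em = [pos[uni[i]] for i in idx_in_uni]
    out[idx_in_uni] = em.values[idx_in_em]
    return ExpressionMatrix(
        out, np.asarray(uni, dtype=object), em.cell_meta.copy(), em.normalized
    )


def write_sparse_triplet(em: ExpressionMatrix, directory: str | Path) -> None:
    """Write the matrix in the 10x sparse-triplet convention (uncompressed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(em.values)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    with open(directory / "features.tsv", "w") as fh:
        for g in em.gene_ids:
            fh.write(f"{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in em.cell_meta.index:
            fh.write(f"{b}\n")
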