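"""Rank-standardized Spearman co-expression networks and their aggregation.

A co-expression network is built per dataset by computing the Spearman
correlation of every gene pair across cells, jointly ranking all entries of
the gene-by-gene matrix (ties averaged) and dividing by the maximum rank.
This maps every network into (0, 1], making networks from datasets of very
different depth and size directly comparable; an aggregate network is the
element-wise mean of many rank-standardized networks and denoises the sparse
signal of any individual dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

_SYMMETRY_TOL = 1e-8


@dataclass
class CoexpressionNetwork:
    """Symmetric gene-by-gene matrix of rank-standardized co-expression.

    ``values`` lies in (0, 1] with diagonal forced to 1; ``gene_ids`` is the
    harmonization universe in universe order.  ``n_cells`` and ``n_datasets``
    carry provenance through aggregation.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    n_cells: int = 0
    n_datasets: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.gene_ids) != n:
            raise ValueError("values must be square and match gene_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("network contains non-finite values")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("network matrix is not symmetric")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in network namespace")
        return int(idx[0])

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset(
                "values", data=self.values, compression="gzip", track_times=False
            )
            fh.create_dataset(
                "gene_ids", data=np.asarray(self.gene_ids, dtype="S"),
                track_times=False,
            )
            fh.attrs["n_cells"] = self.n_cells
            fh.attrs["n_datasets"] = self.n_datasets

    @classmethod
    def from_hdf5(cls, path) -> "CoexpressionNetwork":
        with h5py.File(path, "r") as fh:
            values = fh["values"][...]
            gene_ids = np.array([g.decode() for g in fh["gene_ids"][...]], dtype=object)
            return cls(values, gene_ids, int(fh.attrs["n_cells"]), int(fh.attrs["n_datasets"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def spearman_matrix(em: ExpressionMatrix) -> np.ndarray:
    """Spearman correlation of every gene pair across all cells.

    Zero-variance genes (including zero-padded universe genes) get
    correlation 0 against everything: a neutral value that places them in
    the low tied mass after rank standardization instead of propagating NaN.
    """
    if em.n_cells < 2:
        raise ValueError("need at least 2 cells to compute correlations")
    ranks = rankdata(em.values, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * em.n_cells)
    normed = centered / denom[:, None]
    corr = normed @ normed.T * em.n_cells
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    # exact symmetry regardless of BLAS summation order
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, np.where(constant, 0.0, 1.0))
    return corr


def rank_standardize(
    corr: np.ndarray, gene_ids, n_cells: int = 0
) -> CoexpressionNetwork:
    """Jointly rank all entries of the matrix and divide by the maximum rank.

    Ties receive the average rank, so the output lies in (0, 1] with the
    global maximum mapped exactly to 1.  Ranking the full symmetric matrix
    (diagonal included) keeps the result symmetric; the diagonal is then
    forced to 1.
    """
    corr = np.asarray(corr, dtype=np.float64)
    if np.abs(corr - corr.T).max(initial=0.0) > _SYMMETRY_TOL:
        raise ValueError("rank_standardize requires a symmetric matrix")
    flat = rankdata(corr, axis=None)
    standardized = (flat / flat.size).reshape(corr.shape)
    standardized = (standardized + standardized.T) / 2.0
    np.fill_diagonal(standardized, 1.0)
    return CoexpressionNetwork(standardized, gene_ids, n_cells=n_cells, n_datasets=1)


def build_network(em: ExpressionMatrix) -> CoexpressionNetwork:
    """Spearman correlation followed by rank standardization."""
    net = rank_standardize(spearman_matrix(em), em.gene_ids, n_cells=em.n_cells)
    return net


def aggregate_networks(nets: list[CoexpressionNetwork]) -> CoexpressionNetwork:
    """Element-wise mean of rank-standardized networks sharing a namespace."""
    if not nets:
        raise ValueError("need at least one network to aggregate")
    first = nets[0]
    for net in nets[1:]:
        if len(net.gene_ids) != len(first.gene_ids) or not np.array_equal(
            net.gene_ids, first.gene_ids
        ):
            diff = np.flatnonzero(
                np.asarray(net.gene_ids[: len(first.gene_ids)])
                != np.asarray(first.gene_ids[: len(net.gene_ids)])
            )
            pos = int(diff[0]) if diff.size else min(len(net.gene_ids), len(first.gene_ids))
            raise ValueError(
                f"gene namespace mismatch between networks at position {pos}"
            )
    mean = np.mean([net.values for net in nets], axis=0)
    return CoexpressionNetwork(
        mean,
        first.gene_ids.copy(),
        n_cells=sum(net.n_cells for net in nets),
        n_datasets=sum(net.n_datasets for net in nets),
    )
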