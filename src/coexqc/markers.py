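"""Meta-analytic cell-type markers from recurrent differential expression.

Per dataset, every gene is scored one-vs-rest for every cell type
(log2 fold change of mean CPM, expression-ranking AUROC, one-sided rank-sum
p with BH correction).  Markers are then meta-ranked across datasets by how
often they pass the differential-expression thresholds (recurrence), with
ties broken by the averaged AUROC.  An aggregate-expression predictor (sum
of marker expression per cell, ranked) turns any marker list into a
cell-type classifier whose quality is again an AUROC.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_LOG2FC_MIN = 4.0
DE_FDR_MAX = 0.05
PSEUDOCOUNT_CPM = 1.0


def mann_whitney_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the normalized Mann-Whitney U statistic.

    With ``R0`` the sum of the (average, tie-handling) ranks of the
    positives, ``U = R0 - n0*(n0+1)/2`` and ``AUROC = U / (n0*n1)``: the
    probability that a random positive outranks a random negative, ties
    counting one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    n0 = int(labels.sum())
    n1 = int((~labels).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError(
            f"AUROC undefined: {n0} positives and {n1} negatives"
        )
    ranks = rankdata(scores)
    r0 = ranks[labels].sum()
    u = r0 - n0 * (n0 + 1) / 2.0
    return float(u / (n0 * n1))


def _tie_term(row: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of one gene's expression row."""
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float((t**3 - t).sum())


def compute_markers(
    em: ExpressionMatrix,
    label_col: str = "cell_type",
    dataset: str = "dataset",
    pseudocount: float = PSEUDOCOUNT_CPM,
) -> pd.DataFrame:
    """One-vs-rest differential-expression statistics for every (gene, cell type).

    Returns a table with columns ``gene, cell_type, dataset, log2_fc, auroc,
    p_value, fdr, frac_in, frac_out``.  ``log2_fc`` is the log2 ratio of mean
    CPM with a pseudocount of 1 CPM on both sides; ``auroc`` ranks cells by
    the gene's expression; the p-value is the one-sided (greater-in-type)
    normal-approximate rank-sum test with tie correction, BH-adjusted within
    each cell type.  Cell types with fewer than 2 cells are excluded.
    """
    if em.normalized != "cpm":
        warnings.warn(
            "compute_markers expects CPM-normalized input; got counts",
            stacklevel=2,
        )
    if label_col not in em.cell_meta.columns:
        raise ValueError(f"cell_meta lacks a {label_col!r} column")
    labels = em.cell_meta[label_col].to_numpy()
    cell_types = [ct for ct in pd.unique(labels) if not pd.isna(ct)]
    usable = []
    for ct in cell_types:
        if (labels == ct).sum() >= 2:
            usable.append(ct)
        else:
            warnings.warn(f"cell type {ct!r} has < 2 cells; excluded", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 cell types with >= 2 cells each")

    values = em.values
    n_genes, n_cells = values.shape
    ranks = rankdata(values, axis=1)
    tie_terms = np.array([_tie_term(values[g]) for g in range(n_genes)])
    detected = values > 0

    frames = []
    for ct in usable:
        pos = labels == ct
        n0 = int(pos.sum())
        n1 = n_cells - n0
        r0 = ranks[:, pos].sum(axis=1)
        u = r0 - n0 * (n0 + 1) / 2.0
        auroc = u / (n0 * n1)

        mu = n0 * n1 / 2.0
        sigma_sq = (n0 * n1 / 12.0) * (
            (n_cells + 1) - tie_terms / (n_cells * (n_cells - 1))
        )
        sigma = np.sqrt(np.maximum(sigma_sq, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (u - mu - 0.5) / np.where(sigma > 0, sigma, 1.0)
        p = np.where(sigma > 0, norm.sf(z), 1.0)

        mean_in = values[:, pos].mean(axis=1)
        mean_out = values[:, ~pos].mean(axis=1)
        log2_fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

        fdr = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": em.gene_ids,
                    "cell_type": ct,
                    "dataset": dataset,
                    "log2_fc": log2_fc,
                    "auroc": auroc,
                    "p_value": p,
                    "fdr": fdr,
                    "frac_in": detected[:, pos].mean(axis=1),
                    "frac_out": detected[:, ~pos].mean(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_meta_markers(
    stats: Sequence[pd.DataFrame],
    log2_fc_min: float = DE_LOG2FC_MIN,
    fdr_max: float = DE_FDR_MAX,
) -> pd.DataFrame:
    """Meta-rank markers across datasets by recurrent differential expression.

    A gene's recurrence for a cell type is the number of datasets in which it
    passed both thresholds (log2 fold change >= ``log2_fc_min`` and FDR <=
    ``fdr_max``).  Genes are ordered by recurrence (descending), then mean
    AUROC across datasets (descending), then gene id (ascending).  Only cell
    types shared by every input are ranked.
    """
    if not stats:
        raise ValueError("need at least one marker-statistics table")
    shared = set(stats[0]["cell_type"].unique())
    for tab in stats[1:]:
        shared &= set(tab["cell_type"].unique())
    if not shared:
        raise ValueError("no cell types shared across all input datasets")

    combined = pd.concat(stats, ignore_index=True)
    combined = combined[combined["cell_type"].isin(shared)].copy()
    combined["is_de"] = (
        (combined["log2_fc"] >= log2_fc_min) & (combined["fdr"] <= fdr_max)
    )
    grouped = (
        combined.groupby(["cell_type", "gene"], sort=False)
        .agg(
            recurrence=("is_de", "sum"),
            mean_auroc=("auroc", "mean"),
            mean_log2_fc=("log2_fc", "mean"),
        )
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["cell_type", "recurrence", "mean_auroc", "gene"],
        ascending=[True, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    grouped["rank"] = grouped.groupby("cell_type").cumcount() + 1
    return grouped


def top_meta_markers(meta: pd.DataFrame, k: int) -> dict[str, list[str]]:
    """Top-k genes per cell type from a meta-marker ranking."""
    out: dict[str, list[str]] = {}
    for ct, group in meta.groupby("cell_type", sort=False):
        out[str(ct)] = group.nsmallest(k, "rank")["gene"].tolist()
    return out


def top_markers_single_dataset(stats: pd.DataFrame, k: int = 100) -> dict[str, list[str]]:
    """Top-k markers per cell type of one dataset, ranked by AUROC.

    Ties are broken by ascending gene id; if k exceeds the gene count all
    genes are returned with a warning.
    """
    out: dict[str, list[str]] = {}
    for ct, group in stats.groupby("cell_type", sort=False):
        if k > len(group):
            warnings.warn(
                f"k={k} exceeds {len(group)} genes for cell type {ct!r}",
                stacklevel=2,
            )
        ordered = group.sort_values(
            ["auroc", "gene"], ascending=[False, True], kind="stable"
        )
        out[str(ct)] = ordered["gene"].head(k).tolist()
    return out


def aggregate_expression_predict(
    em: ExpressionMatrix,
    marker_genes: Iterable[str],
    target_label: str,
    label_col: str = "cell_type",
) -> float:
    """AUROC of summed marker expression for target-vs-rest cell prediction.

    The expression of the marker genes is summed within each cell and all
    cells are ranked by this aggregate; perfect markers (expressed only in
    the target type) give an AUROC of 1.
    """
    markers = [g for g in marker_genes]
    pos_genes = np.isin(em.gene_ids.astype(str), np.asarray(markers, dtype=str))
    if not pos_genes.any():
        raise ValueError("no marker genes found in the expression matrix")
    labels = em.cell_meta[label_col].to_numpy()
    if target_label not in labels:
        raise ValueError(f"target label {target_label!r} absent from cell_meta")
    scores = em.values[pos_genes].sum(axis=0)
    return mann_whitney_auroc(scores, labels == target_label)


def loo_cross_validate(
    datasets: Sequence[ExpressionMatrix],
    k_list: Sequence[int] = (10,),
    label_col: str = "cell_type",
    dataset_names: Sequence[str] | None = None,
    precomputed_stats: Sequence[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Leave-one-dataset-out marker cross-validation.

    For each left-out dataset, meta-markers are learned from the remaining
    datasets and used as aggregate-expression predictors of the left-out
    cell-type annotations.  Returns a table of (dataset, cell_type, k,
    auroc); cell types absent from a left-out dataset are omitted.
    """
    if len(datasets) < 2:
        raise ValueError("leave-one-out needs at least 2 datasets")
    if dataset_names is None:
        dataset_names = [f"dataset_{i}" for i in range(len(datasets))]
    if precomputed_stats is None:
        stats = [
            compute_markers(em, label_col=label_col, dataset=name)
            for em, name in zip(datasets, dataset_names)
        ]
    else:
        stats = list(precomputed_stats)

    rows = []
    for i, (em, name) in enumerate(zip(datasets, dataset_names)):
        meta = make_meta_markers([s for j, s in enumerate(stats) if j != i])
        present = set(em.cell_meta[label_col].dropna().unique())
        for k in k_list:
            markers_by_type = top_meta_markers(meta, k)
            for ct, markers in markers_by_type.items():
                if ct not in present:
                    continue
                auroc = aggregate_expression_predict(
                    em, markers, ct, label_col=label_col
                )
                rows.append(
                    {"dataset": name, "cell_type": ct, "k": k, "auroc": auroc}
                )
    return pd.DataFrame(rows)
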