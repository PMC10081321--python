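"""Preserved co-expression: does a test network keep the reference network's
top co-expression partners?

For a gene A, the positives are A's top-k (default 10) co-expressed partners
in the reference network; every other gene (excluding A itself) is a
negative.  Genes are then ranked by their co-expression with A in the test
network and the AUROC of that ranking is A's preserved co-expression score.
Identical networks give 1; an unrelated test network gives 0.5 in
expectation.  A gene set's score is the mean over its member genes; the
global score is the mean over all scored genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import mann_whitney_auroc
from .network import CoexpressionNetwork

logger = logging.getLogger(__name__)

DEFAULT_K = 10


@dataclass
class PreservationResult:
    """Per-gene, per-set and global preserved co-expression AUROCs."""

    per_gene: pd.Series
    set_scores: dict[str, float]
    global_score: float
    k: int = DEFAULT_K
    uninformative_genes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "global_score": self.global_score,
            "set_scores": self.set_scores,
            "n_genes_scored": int(self.per_gene.notna().sum()),
            "n_uninformative": len(self.uninformative_genes),
        }


def top_k_partners(
    ref: CoexpressionNetwork, gene: str, k: int = DEFAULT_K
) -> list[str]:
    """The k genes most strongly co-expressed with ``gene`` in the reference.

    The query gene itself is excluded.  Ties at the k-th value are broken by
    ascending gene id, yielding a deterministic cut at exactly k partners.
    """
    gi = ref.gene_index(gene)
    if ref.n_genes <= k:
        raise ValueError(f"network has {ref.n_genes} genes; need more than k={k}")
    row = ref.values[gi].copy()
    ids = ref.gene_ids.astype(str)
    mask = np.ones(ref.n_genes, dtype=bool)
    mask[gi] = False
    order = np.lexsort((ids[mask], -row[mask]))
    return list(ids[mask][order[:k]])


def preserved_auroc(
    ref: CoexpressionNetwork,
    test: CoexpressionNetwork,
    gene: str,
    k: int = DEFAULT_K,
) -> float:
    """Preserved co-expression AUROC for one gene (see module docstring).

    A gene whose test-network row is entirely tied carries no ranking
    information; 0.5 is returned with a warning.
    """
    _check_namespaces(ref, test)
    gi = ref.gene_index(gene)
    positives = top_k_partners(ref, gene, k=k)
    mask = np.ones(ref.n_genes, dtype=bool)
    mask[gi] = False
    scores = test.values[gi][mask]
    ids = ref.gene_ids.astype(str)[mask]
    labels = np.isin(ids, np.asarray(positives, dtype=str))
    if np.ptp(scores) == 0:
        warnings.warn(
            f"gene {gene!r} has an all-tied test row; returning 0.5",
            stacklevel=2,
        )
        return 0.5
    return mann_whitney_auroc(scores, labels)


def _check_namespaces(ref: CoexpressionNetwork, test: CoexpressionNetwork) -> None:
    if ref.n_genes != test.n_genes or not np.array_equal(ref.gene_ids, test.gene_ids):
        raise ValueError(
            "reference and test networks must share an identical gene "
            "namespace (harmonize both to the same universe first)"
        )


def score_preservation(
    ref: CoexpressionNetwork,
    test: CoexpressionNetwork,
    gene_sets: dict[str, list[str]] | None = None,
    k: int = DEFAULT_K,
    genome_wide: bool = True,
) -> PreservationResult:
    """Preserved co-expression at gene, gene-set and genome-wide resolution.

    Scores every gene in any requested set, plus (by default) the full
    namespace.  Set scores are the arithmetic mean of member-gene AUROCs;
    set genes missing from the namespace are logged and excluded; a set
    empty after intersection gets an undefined (NaN) score.  Genes whose
    test row is entirely tied score 0.5 and are flagged uninformative.
    """
    _check_namespaces(ref, test)
    ids = ref.gene_ids.astype(str)
    namespace = set(ids)
    to_score: set[str] = set()
    if genome_wide:
        to_score.update(ids)
    if gene_sets:
        for term, members in gene_sets.items():
            missing = [g for g in members if g not in namespace]
            if missing:
                logger.info(
                    "set %s: %d genes absent from the namespace", term, len(missing)
                )
            to_score.update(g for g in members if g in namespace)

    per_gene = pd.Series(np.nan, index=sorted(to_score), dtype=float)
    uninformative: list[str] = []
    # vectorized scoring: all genes share the candidate construction
    gene_idx = {g: i for i, g in enumerate(ids)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in per_gene.index:
            score = preserved_auroc(ref, test, g, k=k)
            per_gene[g] = score
            gi = gene_idx[g]
            row = test.values[gi]
            if np.ptp(np.delete(row, gi)) == 0:
                uninformative.append(g)

    set_scores: dict[str, float] = {}
    if gene_sets:
        for term, members in gene_sets.items():
            used = [g for g in members if g in namespace]
            set_scores[term] = float(per_gene[used].mean()) if used else float("nan")

    scored = per_gene.dropna()
    global_score = float(scored.mean()) if len(scored) else float("nan")
    return PreservationResult(
        per_gene=per_gene,
        set_scores=set_scores,
        global_score=global_score,
        k=k,
        uninformative_genes=uninformative,
    )


def fine_markers_from_de(
    de_table: pd.DataFrame,
    k: int = 10,
    exclude: dict[str, list[str]] | None = None,
) -> dict[str, list[str]]:
    """Top-k marker sets per cell type from a table of adjusted DE p-values.

    ``de_table`` needs columns ``cell_type``, ``gene`` and ``adj_p``.  Genes
    are taken in ascending adjusted-p order (ties by gene id).  When
    ``exclude`` is given, genes appearing in any excluded collection are
    removed first so the resulting sets are disjoint from it.
    """
    if de_table.empty:
        raise ValueError("empty differential-expression table")
    excluded: set[str] = set()
    if exclude:
        for members in exclude.values():
            excluded.update(members)
    out: dict[str, list[str]] = {}
    for ct, group in de_table.groupby("cell_type", sort=False):
        usable = group[~group["gene"].isin(excluded)]
        if len(usable) < k:
            warnings.warn(
                f"cell type {ct!r} has only {len(usable)} genes; using all",
                stacklevel=2,
            )
        ordered = usable.sort_values(["adj_p", "gene"], kind="stable")
        out[str(ct)] = ordered["gene"].head(k).tolist()
    return out


def reference_percentile(score: float, reference_scores) -> float:
    """Percentile of a score within a reference distribution, in [0, 100].

    Mid-rank convention: 100 * (strictly-below + half of ties) / n.
    """
    ref = np.asarray(list(reference_scores), dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    below = (ref < score).sum()
    ties = (ref == score).sum()
    return float(100.0 * (below + 0.5 * ties) / ref.size)
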