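"""Cell-type modularity of marker co-expression: ordered marker submatrices,
consensus k-means against the perfect marker grouping (ARI), and Ward
dendrogram leaf orders.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .network import CoexpressionNetwork


def marker_submatrix(
    net: CoexpressionNetwork, marker_sets: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Marker-restricted co-expression submatrix with heatmap ordering.

    Rows/columns are the union of the marker sets intersected with the
    network namespace, grouped by set; within each set genes are ordered by
    descending mean co-expression to the other members of the same set (ties
    by ascending gene id).  Returns the submatrix and the gene -> set labels.
    """
    namespace = {g: i for i, g in enumerate(net.gene_ids.astype(str))}
    ordered_genes: list[str] = []
    labels: list[str] = []
    seen: set[str] = set()
    for set_name, members in marker_sets.items():
        used = [g for g in members if g in namespace and g not in seen]
        if not used:
            continue
        idx = np.array([namespace[g] for g in used])
        sub = net.values[np.ix_(idx, idx)]
        if len(used) > 1:
            mean_intra = (sub.sum(axis=1) - np.diag(sub)) / (len(used) - 1)
        else:
            mean_intra = np.zeros(1)
        order = np.lexsort((np.asarray(used), -mean_intra))
        for j in order:
            ordered_genes.append(used[j])
            labels.append(set_name)
            seen.add(used[j])
    if not ordered_genes:
        raise ValueError("marker sets have no overlap with the network namespace")
    idx = np.array([namespace[g] for g in ordered_genes])
    sub = pd.DataFrame(
        net.values[np.ix_(idx, idx)], index=ordered_genes, columns=ordered_genes
    )
    return sub, pd.Series(labels, index=ordered_genes, name="marker_set")


def consensus_kmeans_ari(
    submatrix: pd.DataFrame,
    set_labels: pd.Series,
    k: int = 6,
    repeats: int = 100,
    seed: int | None = 0,
) -> float:
    """ARI between a consensus k-means partition and the marker-set grouping.

    k-means on the submatrix rows is repeated ``repeats`` times with seeded
    single initializations.  The co-clustering frequency matrix over runs
    summarises their consensus; the reported partition is the run whose
    own co-clustering pattern agrees best (highest mean elementwise
    agreement) with that frequency matrix.  The ARI compares it with the
    labeling of genes by their marker set.
    """
    x = submatrix.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds {x.shape[0]} genes")
    if np.ptp(x, axis=0).max(initial=0.0) == 0:
        warnings.warn("all rows identical; ARI is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(repeats):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        partitions.append(km.fit_predict(x))
    n = x.shape[0]
    freq = np.zeros((n, n))
    for part in partitions:
        freq += part[:, None] == part[None, :]
    freq /= repeats
    agreements = [
        float(((part[:, None] == part[None, :]) == (freq >= 0.5)).mean())
        for part in partitions
    ]
    best = partitions[int(np.argmax(agreements))]
    truth = set_labels.loc[submatrix.index].to_numpy()
    return float(adjusted_rand_score(truth, best))


def ward_dendrogram_order(submatrix: pd.DataFrame) -> list[str]:
    """Deterministic leaf order of a Ward dendrogram over co-expression rows.

    Agglomerative clustering with Ward's criterion on Euclidean distances;
    at every internal node the subtree containing the smaller original index
    is placed first, making the leaf order independent of library internals.
    """
    x = submatrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes for a dendrogram")
    z = linkage(x, method="ward")
    n = x.shape[0]

    min_leaf: dict[int, int] = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, _, _) in enumerate(z):
        node = n + step
        a, b = int(a), int(b)
        children[node] = (a, b)
        min_leaf[node] = min(min_leaf[a], min_leaf[b])

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        return _leaves(first) + _leaves(second)

    order = _leaves(n + len(z) - 1)
    return [str(submatrix.index[i]) for i in order]
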