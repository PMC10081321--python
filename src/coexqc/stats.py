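"""Significance machinery: GO-preservation z-test, permutation correlation
test, group comparisons, and hypergeometric GO enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, norm, rankdata
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def go_preservation_ztest(
    per_gene_auroc: pd.Series,
    terms: dict[str, list[str]],
    size_min: int = 20,
    size_max: int = 250,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Sampling-error z-test for term-level preserved co-expression.

    The mean and standard deviation of the per-gene preserved co-expression
    AUROCs over all scored genes define the population.  For a term of
    ``n_GO`` members (after intersecting with the scored genes), the term
    score ``mu_GO`` is compared against the population mean through
    ``Z = (mu_GO - mu_pop) / SE`` with ``SE = SD_pop / sqrt(n_GO)``.  The
    left p-value is the standard-normal CDF of Z (term significantly *not*
    preserved); the right p-value is its complement (term significantly
    preserved).  Both tails are BH-adjusted over the surviving terms and
    thresholded at ``alpha``; terms outside ``[size_min, size_max]`` members
    are excluded.
    """
    scores = per_gene_auroc.dropna()
    mu_pop = float(scores.mean())
    sd_pop = float(scores.std(ddof=0))
    if sd_pop == 0:
        raise ValueError("degenerate population: all per-gene scores identical")
    scored = set(scores.index.astype(str))

    rows = []
    for term, members in terms.items():
        used = [g for g in members if g in scored]
        n_go = len(used)
        if not (size_min <= n_go <= size_max):
            continue
        mu_go = float(scores[used].mean())
        se = sd_pop / np.sqrt(n_go)
        z = (mu_go - mu_pop) / se
        p_left = float(norm.cdf(z))
        rows.append(
            {
                "term": term,
                "n_genes": n_go,
                "mu_term": mu_go,
                "mu_pop": mu_pop,
                "sd_pop": sd_pop,
                "se": se,
                "z": z,
                "p_left": p_left,
                "p_right": 1.0 - p_left,
            }
        )
    if not rows:
        raise ValueError("no terms within the size window")
    out = pd.DataFrame(rows)
    out["fdr_left"] = bh_adjust(out["p_left"])
    out["fdr_right"] = bh_adjust(out["p_right"])
    out["significant_preserved"] = out["fdr_right"] <= alpha
    out["significant_not_preserved"] = out["fdr_left"] <= alpha
    return out


def permutation_corr_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | None = 0,
    method: str = "spearman",
    plus_one: bool = False,
) -> tuple[float, float]:
    """Two-sided permutation test for a correlation coefficient.

    The pairing of one vector is permuted ``n_perm`` times; the p-value is
    the fraction of permuted coefficients whose absolute value reaches the
    observed absolute coefficient.  With ``plus_one`` the (b+1)/(B+1)
    correction is applied instead of the raw count (which can be 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")

    if method == "spearman":
        xr, yr = rankdata(x), rankdata(y)
    elif method == "pearson":
        xr, yr = x.copy(), y.copy()
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")

    def _corr(a, b):
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        return float(a @ b / a.size)

    rho = _corr(xr, yr)
    rng = np.random.default_rng(seed)
    ax = (xr - xr.mean()) / xr.std()
    by = (yr - yr.mean()) / yr.std()
    # permute y's pairing; |rho| is symmetric in which vector is shuffled
    perms = np.array([by[rng.permutation(by.size)] for _ in range(n_perm)])
    null = perms @ ax / ax.size
    hits = int((np.abs(null) >= abs(rho)).sum())
    if plus_one:
        p = (hits + 1) / (n_perm + 1)
    else:
        p = hits / n_perm
    return rho, float(p)


def compare_groups(
    scores_by_group: dict[str, dict[str, tuple]],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney tests over a family of group comparisons.

    ``scores_by_group`` maps a comparison name to ``{"a": values, "b":
    values}``.  The p-value is exact when the smaller group has at most 8
    observations and there are no ties, otherwise the normal approximation
    with continuity correction is used.  BH adjustment is applied across the
    submitted family.
    """
    rows = []
    for name, groups in scores_by_group.items():
        a = np.asarray(groups["a"], dtype=float)
        b = np.asarray(groups["b"], dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"comparison {name!r} has an empty group")
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "comparison": name,
                "n_a": a.size,
                "n_b": b.size,
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"])
    out["significant"] = out["fdr"] <= fdr_max
    return out


def go_enrichment(
    hit_set,
    universe,
    terms: dict[str, list[str]],
    test_size: tuple[int, int] = (10, 1000),
    report_size: tuple[int, int] = (20, 500),
) -> pd.DataFrame:
    """Upper-tail hypergeometric (Fisher) enrichment of a hit set in GO terms.

    Raw p-values are computed for every term whose universe-intersected size
    lies in ``test_size`` and BH-adjusted across that family; the
    ``reportable`` column restricts ranking/reporting to terms within
    ``report_size``.
    """
    universe = set(universe)
    hits = set(hit_set)
    offenders = hits - universe
    if offenders:
        raise ValueError(
            f"hit genes outside the universe: {sorted(offenders)[:10]}"
        )
    m = len(universe)
    n_hits = len(hits)
    rows = []
    for term, members in terms.items():
        in_uni = set(members) & universe
        size = len(in_uni)
        if not (test_size[0] <= size <= test_size[1]):
            continue
        overlap = len(in_uni & hits)
        # P(X >= overlap) drawing n_hits from m with `size` successes
        p = float(hypergeom.sf(overlap - 1, m, size, n_hits))
        rows.append(
            {
                "term": term,
                "term_size": size,
                "overlap": overlap,
                "p_value": p,
                "reportable": report_size[0] <= size <= report_size[1],
            }
        )
    if not rows:
        raise ValueError("no terms within the tested size window")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"])
    return out.sort_values("fdr", kind="stable").reset_index(drop=True)
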