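"""Significance machinery: preservation z-test, permutation correlation,
group comparison, and hypergeometric enrichment."""

import numpy as np
import pandas as pd

from coexqc import (
    compare_groups,
    go_enrichment,
    go_preservation_ztest,
    permutation_corr_test,
)

# Term-level preservation z-test: is a gene set's mean preserved
# co-expression larger than expected from sampling error alone?
rng = np.random.default_rng(0)
per_gene = pd.Series(rng.normal(0.75, 0.08, 2000),
                     index=[f"g{i}" for i in range(2000)])
strong_term = list(per_gene.nlargest(40).index)
random_term = list(rng.choice(per_gene.index, 40, replace=False))
out = go_preservation_ztest(per_gene, {"strong": strong_term, "random": random_term})
print(out[["term", "n_genes", "mu_term", "z", "fdr_right"]].round(4).to_string(index=False))

# Permutation test for a correlation coefficient (10,000 permutations)
x = rng.normal(size=40)
y = 0.8 * x + rng.normal(scale=0.5, size=40)
rho, p = permutation_corr_test(x, y, seed=1)
print(f"\nspearman rho {rho:.3f}, two-sided permutation p {p:.4g}")

# Mann-Whitney comparison of score groups with BH adjustment
cmp = compare_groups({"normal_vs_perturbed": {"a": [0.9, 0.85, 0.88],
                                              "b": [0.6, 0.55, 0.65]}})
print(f"\ngroup comparison p {cmp.iloc[0].p_value:.3f} "
      f"(exact rank-sum, FDR {cmp.iloc[0].fdr:.3f})")

# Hypergeometric enrichment of a hit list in gene sets
universe = [f"g{i}" for i in range(100)]
enr = go_enrichment(universe[:20], universe,
                    {"front": universe[:25], "back": universe[50:90]},
                    test_size=(10, 1000))
print("\n" + enr[["term", "overlap", "p_value", "fdr"]].round(4).to_string(index=False))
# Low right-tail FDR marks sets preserved (z-test) or enriched
# (hypergeometric) beyond chance.
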