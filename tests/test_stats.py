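import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from coexqc import (
    bh_adjust,
    compare_groups,
    go_enrichment,
    go_preservation_ztest,
    permutation_corr_test,
)


class TestGoPreservationZtest:
    def _population(self, seed=0, n=5000, mu=0.8, sd=0.1):
        rng = np.random.default_rng(seed)
        return pd.Series(
            rng.normal(mu, sd, n), index=[f"g{i}" for i in range(n)]
        )

    @staticmethod
    def worked_example_population():
        """Population with mean exactly 0.8, SD_pop exactly 0.1, containing a
        25-gene term whose mean is exactly 0.85 (mirrored by a 0.75 block and
        a symmetric bulk whose spread tops the variance up to 0.01)."""
        term = [f"t{i}" for i in range(25)]
        d = np.sqrt(0.0175)
        pop = pd.concat(
            [
                pd.Series(0.85, index=term),
                pd.Series(0.75, index=[f"m{i}" for i in range(25)]),
                pd.Series(0.8 + d, index=[f"hi{i}" for i in range(25)]),
                pd.Series(0.8 - d, index=[f"lo{i}" for i in range(25)]),
            ]
        )
        return pop, term

    def test_closed_form_worked_example(self):
        # population mu=0.8 sd=0.1, term of 25 genes with mean 0.85:
        # SE = 0.1/5 = 0.02, Z = 2.5, p_R = 1 - Phi(2.5) ~ 0.00621
        pop, term = self.worked_example_population()
        assert pop.mean() == pytest.approx(0.8, abs=1e-15)
        assert pop.std(ddof=0) == pytest.approx(0.1, abs=1e-15)
        out = go_preservation_ztest(pop, {"term": term}, size_min=20, size_max=250)
        row = out.iloc[0]
        assert row.se == pytest.approx(0.02, abs=1e-12)
        assert row.z == pytest.approx(2.5, abs=1e-12)
        assert row.p_right == pytest.approx(1 - norm.cdf(2.5), abs=1e-12)
        assert row.p_right == pytest.approx(0.006209665, abs=1e-9)
        assert row.p_left + row.p_right == pytest.approx(1.0, abs=1e-12)

    def test_exact_z_and_p_from_fixed_moments(self):
        # direct check of the printed arithmetic: SE=0.02, Z=2.5, p_R~0.00621
        se = 0.1 / np.sqrt(25)
        z = (0.85 - 0.8) / se
        assert se == 0.02
        assert z == pytest.approx(2.5)
        assert 1 - norm.cdf(z) == pytest.approx(0.006209665, abs=1e-9)

    def test_term_at_population_mean(self):
        pop = self._population()
        term = list(pop.index[:30])
        pop[term] = pop.mean()  # force mu_GO ~ mu_pop
        pop2 = pop.copy()
        mu = pop2.drop(term).mean()
        pop2[term] = mu
        out = go_preservation_ztest(pop2, {"t": term})
        row = out.iloc[0]
        assert abs(row.z) < 0.2
        assert row.p_left == pytest.approx(1 - row.p_right, abs=1e-12)

    def test_size_window_filter(self):
        pop = self._population()
        terms = {
            "small": list(pop.index[:10]),
            "ok": list(pop.index[:50]),
            "big": list(pop.index[:1000]),
        }
        out = go_preservation_ztest(pop, terms, size_min=20, size_max=250)
        assert list(out.term) == ["ok"]

    def test_null_calibration_uniform_right_p(self):
        pop = self._population(seed=42)
        rng = np.random.default_rng(43)
        terms = {
            f"t{i}": list(rng.choice(pop.index, 50, replace=False))
            for i in range(1000)
        }
        out = go_preservation_ztest(pop, terms, size_min=20, size_max=250)
        ks = kstest(out.p_right, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_population_errors(self):
        pop = pd.Series(0.5, index=[f"g{i}" for i in range(100)])
        with pytest.raises(ValueError, match="degenerate"):
            go_preservation_ztest(pop, {"t": list(pop.index[:30])})


class TestPermutationCorr:
    def test_identical_vectors(self):
        x = np.arange(20, dtype=float)
        rho, p = permutation_corr_test(x, x, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.001

    def test_antimonotone_matches_monotone_under_same_seed(self):
        x = np.arange(20, dtype=float)
        _, p_pos = permutation_corr_test(x, x, seed=11)
        rho, p_neg = permutation_corr_test(x, -x, seed=11)
        assert rho == pytest.approx(-1.0)
        assert p_neg == p_pos

    def test_bit_reproducible(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = permutation_corr_test(x, y, seed=9)
        b = permutation_corr_test(x, y, seed=9)
        assert a == b

    def test_invariant_to_which_vector_is_permuted(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rho_xy, _ = permutation_corr_test(x, y, seed=3)
        rho_yx, _ = permutation_corr_test(y, x, seed=3)
        assert rho_xy == pytest.approx(rho_yx, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            permutation_corr_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_plus_one_correction_never_zero(self):
        x = np.arange(20, dtype=float)
        _, p = permutation_corr_test(x, x, seed=0, plus_one=True)
        assert p > 0


class TestCompareGroups:
    def test_exact_rank_sum_enumeration(self):
        # {1,2,3} vs {4,5,6}: U=0, two-sided exact p = 2/20 = 0.1
        out = compare_groups({"cmp": {"a": [1, 2, 3], "b": [4, 5, 6]}})
        assert out.iloc[0].p_value == pytest.approx(0.1)
        assert out.iloc[0].u_statistic == 0.0

    def test_identical_groups(self):
        out = compare_groups({"cmp": {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}})
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_bh_fixed_point(self):
        p = np.full(7, 0.05)
        assert np.allclose(bh_adjust(p), 0.05)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups({"cmp": {"a": [], "b": [1.0]}})


class TestGoEnrichment:
    def test_closed_form_worked_example(self):
        # universe 10, hits 5, term 4, overlap 4 -> C(4,4)C(6,1)/C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        hits = universe[:5]
        terms = {"t": universe[:4]}
        out = go_enrichment(hits, universe, terms, test_size=(1, 1000))
        assert out.iloc[0].p_value == pytest.approx(6 / 252, abs=1e-12)

    def test_trivial_term_probabilities(self):
        universe = [f"g{i}" for i in range(10)]
        hits = universe[:5]
        out = go_enrichment(
            hits,
            universe,
            {"none": [universe[9]], "all": universe},
            test_size=(1, 1000),
        )
        by_term = out.set_index("term")
        assert by_term.loc["none"].p_value == pytest.approx(1.0)  # P(X >= 0)
        assert by_term.loc["all"].p_value == pytest.approx(1.0)   # overlap = |hits|

    def test_hits_outside_universe_error(self):
        with pytest.raises(ValueError, match="outside"):
            go_enrichment(["zz"], ["g1"], {"t": ["g1"]})

    def test_report_size_flag(self):
        universe = [f"g{i}" for i in range(600)]
        terms = {"small": universe[:12], "mid": universe[:100]}
        out = go_enrichment(universe[:30], universe, terms)
        by_term = out.set_index("term")
        assert not by_term.loc["small"].reportable
        assert by_term.loc["mid"].reportable
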