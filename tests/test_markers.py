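import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import pair_counting_auroc
from coexqc import (
    ExpressionMatrix,
    aggregate_expression_predict,
    compute_markers,
    cpm_normalize,
    loo_cross_validate,
    make_meta_markers,
    mann_whitney_auroc,
    simulate_dataset,
    SimulationConfig,
    top_markers_single_dataset,
    top_meta_markers,
)


class TestMannWhitneyAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([4, 3, 2, 1], [1, 1, 0, 0], 1.0),      # perfect separation
            ([4, 3, 2, 1], [0, 0, 1, 1], 0.0),      # perfectly wrong
            ([3, 1, 2, 4], [1, 0, 1, 0], 0.5),      # 2 of 4 pairs won
            ([5, 5, 5, 5], [1, 0, 1, 0], 0.5),      # total tie
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert mann_whitney_auroc(scores, np.array(labels, bool)) == expected

    def test_one_class_empty_is_an_error_not_a_score(self):
        with pytest.raises(ValueError, match="undefined"):
            mann_whitney_auroc([1.0, 2.0], np.array([True, True]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 50)
        # integer scores force ties
        scores = rng.integers(0, 10, size=n).astype(float)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
        assert mann_whitney_auroc(scores, labels) == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12
        )

    def test_complementarity(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 6, 30).astype(float)
        labels = rng.random(30) < 0.4
        if labels.any() and not labels.all():
            a = mann_whitney_auroc(scores, labels)
            b = mann_whitney_auroc(scores, ~labels)
            assert a + b == pytest.approx(1.0)


class TestComputeMarkers:
    def _labeled_em(self, values, labels):
        values = np.asarray(values, dtype=float)
        genes = np.array([f"g{i}" for i in range(values.shape[0])], dtype=object)
        meta = pd.DataFrame({"cell_type": labels})
        return ExpressionMatrix(values, genes, meta, normalized="cpm")

    def test_log2fc_pseudocount_arithmetic(self):
        # mean 31 CPM in target, 1 CPM outside -> log2(32/2) = 4
        em = self._labeled_em(
            [[31, 31, 1, 1], [10, 10, 10, 10]], ["A", "A", "B", "B"]
        )
        stats = compute_markers(em)
        row = stats[(stats.gene == "g0") & (stats.cell_type == "A")].iloc[0]
        assert row.log2_fc == pytest.approx(4.0)

    def test_flat_gene_is_null(self):
        em = self._labeled_em(
            [[7, 7, 7, 7], [1, 2, 3, 4]], ["A", "A", "B", "B"]
        )
        stats = compute_markers(em)
        row = stats[(stats.gene == "g0") & (stats.cell_type == "A")].iloc[0]
        assert row.auroc == 0.5
        assert row.log2_fc == 0.0

    def test_exclusive_gene_approaches_one(self):
        em = self._labeled_em(
            [[50, 60, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1]],
            ["A", "A", "B", "B", "B", "B"],
        )
        stats = compute_markers(em)
        row = stats[(stats.gene == "g0") & (stats.cell_type == "A")].iloc[0]
        assert row.auroc == 1.0

    def test_auroc_column_matches_oracle(self, small_sim):
        em = cpm_normalize(small_sim.expression)
        stats = compute_markers(em)
        labels = em.cell_meta["cell_type"].to_numpy()
        rng = np.random.default_rng(0)
        for _ in range(5):
            gi = rng.integers(em.n_genes)
            ct = rng.choice(list(small_sim.marker_map))
            row = stats[(stats.gene == em.gene_ids[gi]) & (stats.cell_type == ct)]
            expected = pair_counting_auroc(em.values[gi], labels == ct)
            assert row.iloc[0].auroc == pytest.approx(expected, abs=1e-12)

    def test_tiny_cell_type_excluded(self):
        em = self._labeled_em(
            np.ones((2, 5)), ["A", "A", "B", "B", "C"]
        )
        with pytest.warns(UserWarning, match="'C'"):
            stats = compute_markers(em)
        assert set(stats.cell_type) == {"A", "B"}


class TestMetaMarkers:
    def _stats(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "cell_type", "dataset", "log2_fc", "auroc", "p_value", "fdr"],
        )

    def test_recurrence_then_auroc_then_gene(self):
        tabs = []
        for d in range(3):
            x_de = True
            y_de = d < 2  # Y passes in 2 of 3 datasets
            tabs.append(
                self._stats(
                    [
                        ("X", "A", f"d{d}", 5.0 if x_de else 0.0, 0.9, 0.001, 0.001 if x_de else 0.9),
                        ("Y", "A", f"d{d}", 5.0 if y_de else 0.0, 0.95, 0.001, 0.001 if y_de else 0.9),
                        ("Z", "A", f"d{d}", 5.0, 0.8, 0.001, 0.001),
                    ]
                )
            )
        meta = make_meta_markers(tabs)
        ordered = meta.sort_values("rank")["gene"].tolist()
        # X recurs 3x (auroc .9) above Z 3x (auroc .8) above Y 2x despite higher auroc
        assert ordered == ["X", "Z", "Y"]

    def test_mean_auroc_breaks_full_recurrence_tie(self):
        tabs = [
            self._stats(
                [
                    ("X", "A", "d0", 5.0, 0.9, 0.001, 0.001),
                    ("Y", "A", "d0", 5.0, 0.8, 0.001, 0.001),
                ]
            )
        ]
        meta = make_meta_markers(tabs)
        assert meta.sort_values("rank")["gene"].tolist() == ["X", "Y"]

    def test_no_shared_cell_types_errors(self):
        a = self._stats([("X", "A", "d0", 5.0, 0.9, 0.001, 0.001)])
        b = self._stats([("X", "B", "d1", 5.0, 0.9, 0.001, 0.001)])
        with pytest.raises(ValueError, match="shared"):
            make_meta_markers([a, b])

    def test_planted_markers_recovered(self, small_sim):
        sims = [
            simulate_dataset(
                SimulationConfig(
                    n_cell_types=3, cells_per_type=60, n_genes=300,
                    markers_per_type=20, seed=s,
                )
            )
            for s in (7, 8, 9)
        ]
        stats = [
            compute_markers(cpm_normalize(s.expression), dataset=f"d{i}")
            for i, s in enumerate(sims)
        ]
        meta = make_meta_markers(stats)
        top = top_meta_markers(meta, 20)
        for ct, planted in sims[0].marker_map.items():
            overlap = len(set(top[ct]) & set(planted)) / len(planted)
            assert overlap >= 0.9


class TestTopMarkersSingleDataset:
    def test_ranked_by_auroc_with_gene_tiebreak(self):
        stats = pd.DataFrame(
            {
                "gene": ["b", "a", "c"],
                "cell_type": "A",
                "auroc": [0.9, 0.9, 0.8],
            }
        )
        top = top_markers_single_dataset(stats, k=2)
        assert top["A"] == ["a", "b"]

    def test_k_above_gene_count_returns_all_with_warning(self):
        stats = pd.DataFrame({"gene": ["a"], "cell_type": ["A"], "auroc": [0.9]})
        with pytest.warns(UserWarning):
            top = top_markers_single_dataset(stats, k=100)
        assert top["A"] == ["a"]


class TestAggregatePredictor:
    def test_exclusive_markers_give_one(self, small_sim):
        em = cpm_normalize(small_sim.expression)
        values = em.values.copy()
        markers = small_sim.marker_map["type_0"][:5]
        idx = np.isin(em.gene_ids, markers)
        target = em.cell_meta["cell_type"] == "type_0"
        values[np.ix_(idx, ~target.to_numpy())] = 0.0
        em2 = ExpressionMatrix(values, em.gene_ids, em.cell_meta, "cpm")
        assert aggregate_expression_predict(em2, markers, "type_0") == 1.0

    def test_all_zero_markers_give_half(self, small_sim):
        em = cpm_normalize(small_sim.expression)
        values = em.values.copy()
        markers = small_sim.marker_map["type_0"][:5]
        values[np.isin(em.gene_ids, markers)] = 0.0
        em2 = ExpressionMatrix(values, em.gene_ids, em.cell_meta, "cpm")
        assert aggregate_expression_predict(em2, markers, "type_0") == 0.5

    def test_matches_pair_counting(self, small_sim):
        em = cpm_normalize(small_sim.expression)
        markers = small_sim.marker_map["type_1"][:10]
        scores = em.values[np.isin(em.gene_ids, markers)].sum(axis=0)
        labels = (em.cell_meta["cell_type"] == "type_1").to_numpy()
        assert aggregate_expression_predict(em, markers, "type_1") == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12
        )

    def test_empty_intersection_errors(self, small_sim):
        em = cpm_normalize(small_sim.expression)
        with pytest.raises(ValueError, match="marker"):
            aggregate_expression_predict(em, ["nope"], "type_0")


@pytest.fixture(scope="module")
def loo_world():
    """Two independent simulations of the same labeled world."""
    sims = [
        simulate_dataset(
            SimulationConfig(
                n_cell_types=3, cells_per_type=60, n_genes=300,
                markers_per_type=20, seed=s,
            )
        )
        for s in (11, 12)
    ]
    return sims, [cpm_normalize(s.expression) for s in sims]


class TestLooCrossValidate:

    def test_planted_markers_predict_held_out(self, loo_world):
        _, ems = loo_world
        table = loo_cross_validate(ems, k_list=[10])
        assert (table["auroc"] > 0.9).all()

    def test_missing_cell_type_row_omitted(self, loo_world):
        sims, ems = loo_world
        # drop one cell type from the second dataset
        keep = (ems[1].cell_meta["cell_type"] != "type_2").to_numpy()
        reduced = ems[1].subset_cells(keep)
        table = loo_cross_validate([ems[0], reduced], k_list=[10])
        second = table[table.dataset == "dataset_1"]
        assert "type_2" not in set(second.cell_type)

    def test_shuffled_labels_near_half(self, loo_world):
        _, ems = loo_world
        rng = np.random.default_rng(0)
        meta = ems[1].cell_meta.copy()
        meta["cell_type"] = rng.permutation(meta["cell_type"].to_numpy())
        shuffled = ExpressionMatrix(ems[1].values, ems[1].gene_ids, meta, "cpm")
        table = loo_cross_validate([ems[0], shuffled], k_list=[10])
        second = table[table.dataset == "dataset_1"]
        # null AUROC has sd ~0.05 at these group sizes, and a single shared
        # permutation correlates the per-type deviations
        assert abs(second["auroc"].mean() - 0.5) < 0.1
        assert np.abs(second["auroc"] - 0.5).max() < 0.15

    def test_needs_two_datasets(self, loo_world):
        _, ems = loo_world
        with pytest.raises(ValueError):
            loo_cross_validate(ems[:1])
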