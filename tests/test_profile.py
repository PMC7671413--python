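"""Log-like binning, the six rarity categories, and feature filtering."""

import numpy as np
import pytest

import latticecoda as lc
from latticecoda.profile import CATEGORIES




class TestBuildBins:
    def test_small_range(self):
        bins = lc.build_bins(25)
        assert bins.labels == ("0", "1-10", "11-20", "21-30")

    def test_decade_growth(self):
        bins = lc.build_bins(1500)
        assert "91-100" in bins.labels and "101-200" in bins.labels
        assert bins.labels[-1] == "1001-2000"
        widths = np.array(bins.uppers) - np.array(bins.lowers) + 1
        assert set(widths.tolist()) == {1, 10, 100, 1000}

    def test_assignment(self):
        bins = lc.build_bins(2000)
        for value, label in [(0, "0"), (1, "1-10"), (10, "1-10"), (11, "11-20"),
                             (150, "101-200"), (1500, "1001-2000")]:
            assert bins.labels[bins.assign(value)] == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lc.build_bins(-1)


class TestBinProfile:
    def test_single_sample_percentages(self):
        per, _ = lc.bin_profile(np.array([[0, 0, 5, 500]]))
        row = per.iloc[0]
        assert row["0"] == 50.0 and row["1-10"] == 25.0 and row["401-500"] == 25.0

    def test_rows_sum_to_hundred(self, rng):
        X = rng.integers(0, 3000, size=(8, 40))
        per, _ = lc.bin_profile(X)
        np.testing.assert_allclose(per.sum(axis=1), 100.0, atol=1e-9)

    def test_all_positive_matrix_has_empty_zero_bin(self, rng):
        X = rng.integers(1, 100, size=(5, 30))
        per, _ = lc.bin_profile(X)
        assert (per["0"] == 0.0).all()

    def test_metagenome_zero_bin_dominates(self):
        X = lc.metagenome_like(n_samples=8, n_features=2000, depth=10_000, seed=5)
        _, summ = lc.bin_profile(X)
        assert summ.loc["0", "median"] > 50.0


class TestRelativeAbundance:
    def test_proportions(self):
        np.testing.assert_allclose(
            lc.relative_abundance(np.array([[1, 1, 2]])), [[0.25, 0.25, 0.5]]
        )

    def test_zeros_stay_zero_and_scale_invariant(self):
        a = lc.relative_abundance(np.array([[0, 1, 3]]))
        b = lc.relative_abundance(np.array([[0, 10, 30]]))
        np.testing.assert_allclose(a, b)
        assert a[0, 0] == 0.0

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            lc.relative_abundance(np.array([[0, 0, 0]]))


class TestClassifyTaxa:
    def test_archetype_features(self):
        # columns engineered to hit AAT, ART and CRAT
        X = np.array(
            [
                [2000, 1, 50_000, 47_999],
                [2000, 1, 5, 97_994],
            ],
            dtype=np.int64,
        )
        cats = lc.classify_taxa(X)
        assert cats[0] == "AAT"  # 2% in every sample
        assert cats[1] == "ART"  # 0.001% in every sample
        assert cats[2] == "CRAT"  # 50% in one sample, 0.005% in the other

    def test_partition_property(self, rng):
        X = rng.integers(0, 50, size=(10, 30)) + (rng.random((10, 30)) < 0.2) * 5000
        X[:, 0] += 1  # keep totals positive
        cats = lc.classify_taxa(X)
        assert set(cats) <= set(CATEGORIES)
        assert len(cats) == X.shape[1]

    def test_matches_brute_force_on_random_matrices(self, rng, classify_oracle):
        for _ in range(1000):
            X = rng.integers(0, 60, size=(20, 8)).astype(float)
            X *= 10.0 ** rng.integers(0, 4, size=(20, 8))  # wide dynamic range
            X[:, 0] += 1
            np.testing.assert_array_equal(
                lc.classify_taxa(X), classify_oracle(X)
            )


class TestFilterFeatures:
    def test_max_count_rule(self):
        X = np.array([[0, 5, 100], [1, 5, 200]])  # features in columns
        filtered, summ = lc.filter_features(X, rule="max_count", threshold=2)
        assert filtered.shape[1] == 2
        assert summ.n_zero_cells == 0
        assert summ.n_features == 2

    def test_impossible_threshold_removes_all(self):
        X = np.array([[1, 2], [3, 4]])
        filtered, summ = lc.filter_features(X, rule="rel_abundance", threshold=1.1)
        assert filtered.shape[1] == 0
        assert summ.pct_features == 0.0

    def test_rel_abundance_comparable_to_min_count_ten(self):
        # on survey-like data the 1e-4 relative-abundance filter and the
        # minimum-count-10 filter retain similar feature fractions
        X = lc.metagenome_like(n_samples=20, n_features=3000, depth=30_000, seed=9)
        _, by_rel = lc.filter_features(X, rule="rel_abundance", threshold=1e-4)
        _, by_cnt = lc.filter_features(X, rule="max_count", threshold=10)
        assert abs(by_rel.pct_features - by_cnt.pct_features) < 25.0

    def test_monotone_in_threshold(self, rng):
        X = rng.integers(0, 300, size=(10, 50))
        prev = None
        for t in (2, 10, 50, 150):
            _, summ = lc.filter_features(X, rule="max_count", threshold=t)
            if prev is not None:
                assert summ.n_sequences <= prev.n_sequences
                assert summ.n_features <= prev.n_features
                assert summ.n_zero_cells <= prev.n_zero_cells
                assert summ.n_cells_2_to_9 <= prev.n_cells_2_to_9
            prev = summ


class TestCategorySummary:
    def test_single_category_equals_whole_matrix(self):
        X = np.array([[500, 490], [505, 495]])
        cats = lc.classify_taxa(X)
        assert set(cats) == {"AAT"}
        summ = lc.category_summary(X, cats)
        assert summ["n_sequences"].iloc[0] == X.sum()
        assert summ["pct_sequences"].iloc[0] == 100.0

    def test_category_totals_sum_to_matrix_totals(self, rng):
        X = rng.integers(0, 50, size=(10, 40)) + (rng.random((10, 40)) < 0.1) * 8000
        X[:, 0] += 1
        cats = lc.classify_taxa(X)
        summ = lc.category_summary(X, cats)
        assert summ["n_sequences"].sum() == X.sum()
        assert summ["n_features"].sum() == X.shape[1]
        assert summ["n_zero_cells"].sum() == (X == 0).sum()

    def test_rare_categories_dominate_survey_data(self):
        X = lc.metagenome_like(n_samples=15, n_features=3000, depth=20_000, seed=3)
        cats = lc.classify_taxa(X)
        summ = lc.category_summary(X, cats).set_index("category")
        rare = summ.reindex(["ART", "CRT"])["n_features"].fillna(0).sum()
        assert rare / X.shape[1] > 0.5
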