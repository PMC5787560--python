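import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronobiome.io_ingest import ValidationError
from chronobiome.preprocess import (
    expected_richness,
    filter_rare_taxa,
    log_scale,
    moving_average,
    normalize_relative,
    quartile_segregate,
    rarefaction_curve,
    rarefy,
)
from conftest import make_dataset


class TestNormalizeRelative:
    def test_proportions(self):
        ds = normalize_relative(make_dataset([[2.0], [3.0], [5.0]]))
        np.testing.assert_allclose(ds.abundance[:, 0], [0.2, 0.3, 0.5])
        assert ds.normalization == "relative"

    def test_all_columns_sum_to_one(self, small_dataset):
        ds = normalize_relative(small_dataset)
        np.testing.assert_allclose(ds.abundance.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_column_warns_and_stays_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            ds = normalize_relative(make_dataset([[0.0, 1.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(ds.abundance[:, 0], 0.0)

    def test_double_normalization_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            normalize_relative(normalize_relative(small_dataset))


class TestRarefy:
    def test_columns_sum_to_depth(self, small_dataset):
        ds = rarefy(small_dataset, depth=50, seed=1)
        assert np.all(ds.abundance.sum(axis=0) == 50)
        assert ds.normalization == "rarefied:50"

    def test_seed_determinism(self, small_dataset):
        a = rarefy(small_dataset, 40, seed=9).abundance
        b = rarefy(small_dataset, 40, seed=9).abundance
        np.testing.assert_array_equal(a, b)

    def test_depth_equal_to_total_is_identity(self):
        ds = make_dataset([[10.0], [5.0], [0.0]])
        out = rarefy(ds, 15, seed=0)
        np.testing.assert_array_equal(out.abundance[:, 0], [10, 5, 0])

    def test_single_taxon_forced(self):
        ds = make_dataset([[1000.0], [0.0], [0.0]])
        out = rarefy(ds, 100, seed=0)
        np.testing.assert_array_equal(out.abundance[:, 0], [100, 0, 0])

    def test_shallow_columns_dropped_with_warning(self):
        ds = make_dataset([[100.0, 3.0], [50.0, 2.0]])
        with pytest.warns(UserWarning, match="S1"):
            out = rarefy(ds, 20, seed=0)
        assert out.n_times == 1

    def test_non_integer_counts_rejected(self):
        ds = make_dataset([[0.5, 1.2], [0.5, 0.8]])
        with pytest.raises(ValidationError, match="integer"):
            rarefy(ds, 1, seed=0)


class TestRarefactionCurve:
    def test_full_depth_equals_observed_richness(self):
        ds = make_dataset([[8.0], [4.0], [0.0], [3.0]])
        curve = rarefaction_curve(ds, "S0", depths=[15], replicates=5, seed=0)
        assert curve.mean_richness[0] == 3

    def test_single_taxon_flat_at_one(self):
        ds = make_dataset([[30.0], [0.0]])
        curve = rarefaction_curve(ds, "S0", depths=[1, 5, 30], replicates=4, seed=0)
        np.testing.assert_array_equal(curve.mean_richness, 1.0)

    def test_depth_above_total_rejected(self):
        ds = make_dataset([[5.0], [5.0]])
        with pytest.raises(ValueError, match="depth"):
            rarefaction_curve(ds, "S0", depths=[11], seed=0)

    def test_matches_hypergeometric_expectation(self):
        # 10 taxa with 6 reads each; compare the Monte-Carlo mean to the
        # closed-form expected richness within 3 Monte-Carlo standard errors
        counts = np.full(10, 6.0)
        ds = make_dataset(counts[:, None])
        reps = 400
        depths = [1, 5, 15, 30, 45, 60]
        curve = rarefaction_curve(ds, "S0", depths, replicates=reps, seed=2)
        for d, mean in zip(depths, curve.mean_richness):
            exact = expected_richness(counts.astype(int), d)
            # richness is a sum of 10 indicators; bound its sd loosely
            se = np.sqrt(10 * 0.25 / reps)
            assert abs(mean - exact) <= 3 * se + 1e-9

    def test_mean_richness_non_decreasing(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.integers(0, 30, size=(12, 1)).astype(float))
        total = int(ds.abundance.sum())
        curve = rarefaction_curve(
            ds, "S0", depths=[1, total // 4, total // 2, total],
            replicates=200, seed=3,
        )
        assert np.all(np.diff(curve.mean_richness) >= -0.2)  # MC tolerance


class TestFilterRareTaxa:
    def test_cutoff_zero_identity(self, small_dataset):
        assert filter_rare_taxa(small_dataset, 0.0).taxa == small_dataset.taxa

    def test_cutoff_semantics_at_70_percent(self):
        seven = [1.0] * 7 + [0.0] * 3
        six = [1.0] * 6 + [0.0] * 4
        ds = make_dataset([seven, six], taxa=["seven", "six"])
        kept = filter_rare_taxa(ds, 0.7).taxa
        assert kept == ["seven"]

    def test_cutoff_one_is_core(self):
        ds = make_dataset([[1.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
        assert filter_rare_taxa(ds, 1.0).taxa == ["tax0"]

    @given(
        c1=st.floats(0, 1),
        c2=st.floats(0, 1),
        data=st.integers(0, 2**30),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, c1, c2, data):
        if c1 > c2:
            c1, c2 = c2, c1
        rng = np.random.default_rng(data)
        ds = make_dataset((rng.random((8, 10)) < 0.5).astype(float))
        loose = set(filter_rare_taxa(ds, c1).taxa)
        strict = set(filter_rare_taxa(ds, c2).taxa)
        assert strict <= loose

    def test_bad_cutoff(self, small_dataset):
        with pytest.raises(ValueError):
            filter_rare_taxa(small_dataset, 1.5)


class TestLogScale:
    def test_values_and_monotonicity(self):
        ds = make_dataset([[0.0, 99.0, 5.0]])
        out = log_scale(ds, pseudocount=1)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(2.0)
        assert out[0, 0] < out[0, 2] < out[0, 1]
        # original untouched
        assert ds.abundance[0, 1] == 99.0

    def test_default_pseudocount_for_proportions(self):
        ds = make_dataset([[0.9, 0.5], [0.1, 0.5]], normalization="relative")
        out = log_scale(ds)
        assert np.all(np.isfinite(out))


class TestMovingAverage:
    @pytest.mark.parametrize(
        "series,window,expected",
        [
            ([1, 2, 3, 4], 2, [1, 1.5, 2.5, 3.5]),
            ([5, 5, 5], 3, [5, 5, 5]),
            ([1, 2, 3], 1, [1, 2, 3]),
        ],
    )
    def test_trailing_mean(self, series, window, expected):
        np.testing.assert_allclose(moving_average(series, window), expected)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            moving_average([1, 2], 0)


class TestQuartileSegregate:
    def test_even_split_of_eight(self):
        ds = make_dataset(np.arange(8, dtype=float)[:, None] * [[1.0, 1.0]])
        q = quartile_segregate(ds)
        from collections import Counter

        assert Counter(q.values()) == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert q["tax7"] == "Q4" and q["tax0"] == "Q1"

    def test_top_quartile_contains_largest_means(self):
        rng = np.random.default_rng(11)
        means = np.exp(rng.normal(0, 2, size=100))
        ds = make_dataset(np.repeat(means[:, None], 3, axis=1))
        q = quartile_segregate(ds)
        top = {t for t, v in q.items() if v == "Q4"}
        expected = {ds.taxa[i] for i in np.argsort(means)[-25:]}
        assert top == expected

    def test_ties_deterministic(self):
        ds = make_dataset(np.ones((4, 3)))
        assert quartile_segregate(ds) == quartile_segregate(ds)

    def test_fewer_than_four_taxa_single_group(self):
        with pytest.warns(UserWarning):
            q = quartile_segregate(make_dataset(np.ones((3, 2))))
        assert set(q.values()) == {"Q1"}
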