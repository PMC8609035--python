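"""Normalization, urbanization index and feature-grouping tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radflow import (FeatureGrouping, FeatureTable, ValidationError,
                     apply_normalization, normalize_adjusted_zscore,
                     normalize_logistic_zscore, normalize_minmax_log,
                     normalize_percentile, normalize_table, reduce_features,
                     urbanization_index, ward_group_features)

nonneg_feature = st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=40)


class TestMinMax:
    def test_log_spaced_values(self):
        out, _ = normalize_minmax_log(np.array([0.0, np.e - 1, np.e ** 2 - 1]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_endpoints(self):
        x = np.array([3.0, 10.0, 7.0, 250.0])
        out, _ = normalize_minmax_log(x)
        assert out[np.argmin(x)] == 0.0 and out[np.argmax(x)] == 1.0
        assert ((out >= 0) & (out <= 1)).all()

    def test_constant_feature_warns_all_zero(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out, _ = normalize_minmax_log(np.array([5.0, 5.0, 5.0]))
        assert (out == 0).all()


class TestAdjustedZ:
    def test_closed_form_three_points(self):
        # log1p values [0, 1, 2]: population sigma = sqrt(2/3)
        x = np.array([0.0, np.e - 1, np.e ** 2 - 1])
        sigma = np.sqrt(2.0 / 3.0)
        out, _ = normalize_adjusted_zscore(x)
        assert np.allclose(out, [0.0, sigma, 1.0 / sigma + sigma], atol=1e-12)
        assert out[1] == pytest.approx(0.8165, abs=1e-4)
        assert out[2] == pytest.approx(2.0412, abs=1e-4)

    def test_low_values_clip_to_zero(self):
        # z + sigma < 0 for the smallest value when sigma < 1
        x = np.expm1(np.array([0.0, 0.5, 1.0]))  # sigma = sqrt(1/6) < 1
        out, stats = normalize_adjusted_zscore(x)
        assert stats["log_sd"] < 1
        assert out[0] == 0.0

    def test_one_shift_mode_clips_one_sigma_below_mean(self):
        # with the +1 translation, clipping happens exactly one sigma below
        x = np.array([0.0, 0.0, 0.0, 1e6, 1e6, 1e6])
        out, _ = normalize_adjusted_zscore(x, shift="one")
        assert (out[:3] == 0.0).all()  # z = -1 at the low block
        assert (out[3:] == 2.0).all()  # z = +1 shifted to 2

    def test_value_at_mean_maps_to_sigma(self):
        x = np.expm1(np.array([1.0, 2.0, 3.0]))  # log1p values 1,2,3, mean 2
        out, stats = normalize_adjusted_zscore(x)
        assert out[1] == pytest.approx(stats["log_sd"], rel=1e-12)

    def test_constant_feature_all_zero(self):
        with pytest.warns(RuntimeWarning):
            out, _ = normalize_adjusted_zscore(np.array([4.0, 4.0]))
        assert (out == 0).all()


class TestLogisticZ:
    def test_mean_maps_to_half(self):
        x = np.expm1(np.array([1.0, 2.0, 3.0]))
        out, _ = normalize_logistic_zscore(x)
        assert out[1] == pytest.approx(0.5, rel=1e-12)

    def test_raw_mode_matches_printed_formula(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        out, _ = normalize_logistic_zscore(x, on_log=False)
        z = (x - x.mean()) / x.std()
        assert np.allclose(out, 1.0 / (1.0 + np.exp(-z)), rtol=1e-12)

    def test_exact_one_sigma_value(self):
        # any value whose z-score is exactly 1 maps to 1/(1+e^-1) = 0.73106
        x = np.array([10.0, 20.0, 30.0, 40.0])
        out, stats = normalize_logistic_zscore(x, on_log=False)
        probe = stats["mean"] + stats["sd"]
        from radflow.features import _apply_logistic_z
        val = _apply_logistic_z(stats, np.array([probe]))[0]
        assert val == pytest.approx(0.73106, abs=1e-5)

    def test_strictly_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 100, 20))
        for on_log in (True, False):
            out, _ = normalize_logistic_zscore(x, on_log=on_log)
            assert (np.diff(out) > 0).all()
            assert ((out > 0) & (out < 1)).all()

    def test_constant_feature_all_half(self):
        with pytest.warns(RuntimeWarning):
            out, _ = normalize_logistic_zscore(np.array([7.0, 7.0, 7.0]))
        assert (out == 0.5).all()


class TestPercentile:
    def test_tied_example(self):
        out, _ = normalize_percentile(np.array([10.0, 20.0, 20.0, 40.0]))
        assert np.allclose(out, [0.0, 0.5, 0.5, 1.0])

    def test_strictly_increasing(self):
        out, _ = normalize_percentile(np.array([3.0, 5.0, 9.0, 11.0]))
        assert (np.diff(out) > 0).all()

    def test_all_equal_maps_to_half(self):
        out, _ = normalize_percentile(np.array([5.0, 5.0, 5.0]))
        assert (out == 0.5).all()


@pytest.mark.parametrize("method", ["minmax", "adjusted_z", "logistic_z", "percentile"])
class TestNormalizationProperties:
    def test_refit_reproduces_training_data(self, method):
        rng = np.random.default_rng(17)
        vals = np.column_stack([rng.uniform(0, 1000, 25),
                                rng.integers(0, 50, 25).astype(float)])
        table = FeatureTable(np.arange(25), ["a", "b"], vals)
        norm = normalize_table(table, method)
        again = apply_normalization(norm, table)
        assert np.allclose(norm.values, again.values, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=nonneg_feature)
    def test_order_preserving(self, method, data):
        x = np.asarray(data)
        table = FeatureTable(np.arange(len(x)), ["f"], x[:, None])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = normalize_table(table, method).values[:, 0]
        order = np.argsort(x, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()


class TestUrbanizationIndex:
    def _norm(self, values, names):
        from radflow import NormalizedFeatureTable
        return NormalizedFeatureTable(np.arange(len(values)), names,
                                      np.asarray(values, dtype=float), "none", {})

    def test_zero_weights_zero_index(self):
        norm = self._norm([[0.3, 0.7], [0.1, 0.9]], ["a", "b"])
        assert (urbanization_index(norm, [0.0, 0.0]) == 0).all()

    def test_single_feature_identity(self):
        norm = self._norm([[0.3], [0.8]], ["a"])
        assert np.allclose(urbanization_index(norm, [1.0]), [0.3, 0.8])

    def test_hand_dot_product(self):
        norm = self._norm([[0.2, 0.1], [0.4, 0.3]], ["a", "b"])
        assert np.allclose(urbanization_index(norm, np.array([2.0, -1.0])), [0.3, 0.5])

    def test_missing_weight_named_in_error(self):
        norm = self._norm([[0.2, 0.1]] * 2, ["a", "b"])
        with pytest.raises(ValidationError, match="b"):
            urbanization_index(norm, {"a": 1.0})


class TestWardGrouping:
    def _table(self, cols):
        names = [f"f{i}" for i in range(len(cols))]
        return FeatureTable(np.arange(len(cols[0])), names, np.column_stack(cols))

    def test_identical_columns_share_group(self):
        c = np.array([1.0, 5.0, 2.0, 9.0])
        t = self._table([c, c.copy(), np.array([100.0, 2.0, 30.0, 4.0])])
        g = ward_group_features(t, 2, exclude=())
        assert g.groups["f0"] == g.groups["f1"] != g.groups["f2"]

    def test_singleton_groups(self):
        t = self._table([np.array([1.0, 2.0]), np.array([5.0, 3.0])])
        g = ward_group_features(t, 2, exclude=())
        assert len(set(g.groups.values())) == 2

    def test_scalar_multiples_cocluster(self):
        # after standardization scalar multiples are identical vectors
        base = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        t = self._table([base, 7.0 * base, np.array([9.0, 1.0, 8.0, 2.0, 7.0])])
        g = ward_group_features(t, 2, exclude=())
        assert g.groups["f0"] == g.groups["f1"] != g.groups["f2"]

    def test_invalid_n_groups(self):
        t = self._table([np.array([1.0, 2.0])])
        with pytest.raises(ValidationError):
            ward_group_features(t, 0, exclude=())


class TestReduceFeatures:
    def _table(self):
        return FeatureTable(np.array(["x", "y"]), ["population", "A", "B", "C"],
                            np.array([[100.0, 1.0, 3.0, 5.0],
                                      [200.0, 2.0, 4.0, 6.0]]))

    def test_merge_all_gives_poi_count(self):
        t = self._table()
        g = FeatureGrouping("clustered", {"A": "poi", "B": "poi", "C": "poi"})
        out = reduce_features(t, g, "merged")
        assert out.feature_names == ["population", "poi"]
        assert np.allclose(out.column("poi"), [9.0, 12.0])

    def test_merged_conserves_total_count(self):
        t = self._table()
        g = FeatureGrouping("clustered", {"A": "g1", "B": "g1", "C": "g2"})
        out = reduce_features(t, g, "merged")
        amen_before = t.values[:, 1:].sum(axis=1)
        amen_after = np.sum([out.column(c) for c in out.feature_names
                             if c != "population"], axis=0)
        assert np.allclose(amen_before, amen_after)

    def test_pairwise_merge_example(self):
        t = FeatureTable(np.array(["x", "y"]), ["A", "B", "C"],
                         np.array([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0]]))
        g = FeatureGrouping("clustered", {"A": "g1", "B": "g1", "C": "g2"})
        out = reduce_features(t, g, "merged")
        assert np.allclose(out.column("g1"), [4.0, 6.0])
        assert np.allclose(out.column("g2"), [5.0, 6.0])

    def test_filtered_singletons_identity(self):
        t = self._table()
        g = FeatureGrouping("clustered", {"A": "gA", "B": "gB", "C": "gC"},
                            {"gA": "A", "gB": "B", "gC": "C"})
        out = reduce_features(t, g, "filtered")
        assert sorted(out.feature_names) == sorted(t.feature_names)
        for name in t.feature_names:
            assert np.allclose(out.column(name), t.column(name))

    def test_unknown_mode_rejected(self):
        t = self._table()
        g = FeatureGrouping("clustered", {"A": "g", "B": "g", "C": "g"})
        with pytest.raises(ValidationError, match="mode"):
            reduce_features(t, g, "bogus")

    def test_representative_must_belong_to_group(self):
        with pytest.raises(ValidationError):
            FeatureGrouping("clustered", {"A": "g1", "B": "g2"}, {"g1": "B"})
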