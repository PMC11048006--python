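"""Standardisation, correlation filter, importance selection, SMOTE."""

import numpy as np
import pandas as pd
import pytest

from subgrade.prep import (
    BalancingError,
    ConstantInputError,
    correlation_filter,
    importance_select,
    pearson_r,
    smote,
    zscore_apply,
    zscore_fit,
)


class TestZScore:
    def test_self_standardisation(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, size=(40, 6)), columns=list("abcdef"))
        params = zscore_fit(table)
        z = zscore_apply(params, table)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-9)

    def test_population_sigma_hand_value(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [4.0]})
        z = zscore_apply(zscore_fit(train), test)
        assert z.iloc[0, 0] == pytest.approx(2.4495, abs=1e-4)

    def test_sample_sigma_variant(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [4.0]})
        z = zscore_apply(zscore_fit(train, population_sd=False), test)
        assert z.iloc[0, 0] == pytest.approx(2.0)

    def test_constant_feature_maps_to_zero_with_flag(self):
        train = pd.DataFrame({"c": [7.0, 7.0, 7.0], "v": [1.0, 2.0, 3.0]})
        params = zscore_fit(train)
        assert params.constant_features == ["c"]
        z = zscore_apply(params, train)
        assert (z["c"] == 0.0).all()


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_r(np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestCorrelationFilter:
    def test_duplicate_column_dropped_once(self, rng):
        x = rng.normal(size=30)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        report = correlation_filter(table)
        assert report.kept == ["a", "c"]
        assert [d[0] for d in report.dropped_by_correlation] == ["b"]

    def test_independent_features_all_kept(self, rng):
        table = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        assert correlation_filter(table).kept == ["a", "b", "c"]

    def test_matches_exhaustive_order_rule(self, rng):
        # four features with known structure: b ~ a, d ~ c, others independent
        a = rng.normal(size=100)
        c = rng.normal(size=100)
        table = pd.DataFrame(
            {"a": a, "b": a + 0.1 * rng.normal(size=100), "c": c, "d": -c}
        )
        report = correlation_filter(table, threshold=0.8)
        # oracle: scan in order, drop the later member of offending pairs
        kept = []
        for name in table.columns:
            if all(abs(np.corrcoef(table[k], table[name])[0, 1]) <= 0.8 for k in kept):
                kept.append(name)
        assert report.kept == kept == ["a", "c"]
        surviving = table[report.kept].corr().abs().to_numpy()
        assert (surviving[np.triu_indices_from(surviving, 1)] <= 0.8).all()


class TestImportanceSelect:
    def test_informative_feature_ranked_first(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = (X["c"] > 0).astype(int).to_numpy()
        report = importance_select(X, y, k=2, seed=0)
        assert report.kept_by_importance[0][0] == "c"

    def test_k_equals_feature_count_is_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, size=50)
        report = importance_select(X, y, k=4, seed=0)
        assert sorted(report.kept) == list("abcd")

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 6)))
        X.columns = [f"f{i}" for i in range(6)]
        y = rng.integers(0, 2, size=60)
        r1 = importance_select(X, y, k=3, seed=7)
        r2 = importance_select(X, y, k=3, seed=7)
        assert r1.kept == r2.kept

    def test_k_clamped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.integers(0, 2, size=30)
        with pytest.warns(UserWarning, match="clamp"):
            report = importance_select(X, y, k=10, seed=0)
        assert report.k_selected == 3


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        Xb, yb = smote(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_two_point_minority_fills_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10.0, 0.0]] * 8)
        y = np.array([1, 1] + [0] * 8)
        Xb, yb = smote(X, y, k_neighbours=1, seed=3)
        assert (yb == 1).sum() == (yb == 0).sum() == 8
        synthetic = Xb[10:]
        # every synthetic point lies on the segment between the two minority points
        np.testing.assert_allclose(synthetic[:, 0], synthetic[:, 1], atol=1e-12)
        assert ((synthetic[:, 0] >= 0.0) & (synthetic[:, 0] <= 1.0)).all()

    def test_originals_preserved_and_counts_equal(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([1] * 9 + [0] * 21)
        Xb, yb = smote(X, y, seed=1)
        np.testing.assert_array_equal(Xb[:30], X)
        assert (yb == 0).sum() == (yb == 1).sum() == 21

    def test_tiny_minority_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(BalancingError):
            smote(X, y, seed=0)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([1] * 9 + [0] * 21)
        X1, _ = smote(X, y, seed=5)
        X2, _ = smote(X, y, seed=5)
        np.testing.assert_array_equal(X1, X2)


class TestReportSerialisation:
    def test_scaler_json_round_trip(self):
        import json

        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        params = zscore_fit(train)
        data = json.loads(params.to_json())
        assert data["mean"]["a"] == 2.0
        assert data["constant_features"] == ["b"]

    def test_selection_report_json(self, rng):
        import json

        x = rng.normal(size=40)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=40)})
        report = correlation_filter(table)
        data = json.loads(report.to_json())
        assert data["threshold_r"] == 0.8
        assert data["dropped_by_correlation"][0]["feature"] == "b"
        assert data["kept"] == ["a", "c"]
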