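"""Classifier zoo contracts and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

from subgrade.evaluate import MetricsReport
from subgrade.models import (
    ALL_REGIONS,
    ExperimentGrid,
    GridCell,
    ModelConfigError,
    ModelSpec,
    PrepConfig,
    SplitSpec,
    build_estimator,
    default_specs,
    external_validate,
    model_names,
    predict,
    run_grid,
    train_model,
)
from subgrade.subregions import AlignmentError


def separable_data(rng, n=40, gap=8.0):
    X = np.vstack(
        [rng.normal(-gap / 2, 1.0, size=(n // 2, 4)), rng.normal(gap / 2, 1.0, size=(n // 2, 4))]
    )
    y = np.repeat([0, 1], n // 2)
    return X, y


def region_tables(rng, n=36, n_features=8, regions=ALL_REGIONS):
    """Synthetic per-region feature tables sharing one subject index."""
    y = np.tile([0, 1], n // 2)
    tables = {}
    for region in regions:
        X = rng.normal(size=(n, n_features))
        X[:, 0] += 2.5 * y  # informative feature
        t = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
        t["grade_label"] = y
        t.index = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
        tables[region] = t
    return tables


FAST_SPECS = [
    ModelSpec("SVM"),
    ModelSpec("RF", {"n_estimators": 25}),
    ModelSpec("NB"),
    ModelSpec("LR"),
]


class TestTrainPredict:
    @pytest.mark.parametrize("name", model_names(include_lstm=True))
    def test_every_model_fits_separable_data(self, name, rng):
        X, y = separable_data(rng)
        overrides = {"LSTM": {"epochs": 150}, "AdaBoost": {"n_estimators": 5, "rf_n_estimators": 11}}
        spec = ModelSpec(name, overrides.get(name, {}))
        model = train_model(spec, X, y)
        labels, scores = predict(model, X)
        assert (labels == y).mean() >= 0.9
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_labels_are_thresholded_scores(self, rng):
        X, y = separable_data(rng)
        model = train_model(ModelSpec("RF", {"n_estimators": 25}), X, y)
        labels, scores = predict(model, X)
        np.testing.assert_array_equal(labels, (scores >= 0.5).astype(int))

    def test_seeded_forest_is_deterministic(self, rng):
        X, y = separable_data(rng)
        m1 = train_model(ModelSpec("RF", {"n_estimators": 25}), X, y)
        m2 = train_model(ModelSpec("RF", {"n_estimators": 25}), X, y)
        np.testing.assert_array_equal(predict(m1, X)[1], predict(m2, X)[1])

    def test_unknown_model_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelSpec("ResNet")

    def test_non_binary_labels_rejected(self, rng):
        X, _ = separable_data(rng)
        with pytest.raises(ValueError):
            train_model(ModelSpec("NB"), X, np.zeros(len(X)))

    def test_table1_defaults_resolved(self):
        svm = build_estimator(ModelSpec("SVM"))
        assert svm.C == 0.01 and svm.gamma == 0.2 and svm.probability
        rf = build_estimator(ModelSpec("RF"))
        assert rf.n_estimators == 401 and rf.max_depth == 3
        lgbm = build_estimator(ModelSpec("LightGBM"))
        assert lgbm.n_estimators == 9
        cb = build_estimator(ModelSpec("CatBoost"))
        assert cb.n_estimators == 50
        assert len(default_specs(include_lstm=True)) == 11


class TestRunGrid:
    def test_cells_and_split_reuse(self, rng):
        tables = region_tables(rng)
        prep = PrepConfig(k_selected=3)
        grid = run_grid({"c1": tables}, FAST_SPECS, SplitSpec(seed=0), prep)
        assert grid.n_cells == 7 * len(FAST_SPECS)
        # one split per cohort, reused across all regions/models
        assert len(grid.train_index) == 1
        assert len(np.intersect1d(grid.train_index["c1"], grid.test_index["c1"])) == 0
        assert len(grid.train_index["c1"]) + len(grid.test_index["c1"]) == 36

    def test_informative_feature_recovered(self, rng):
        tables = region_tables(rng, n=60)
        grid = run_grid({"c1": tables}, FAST_SPECS, SplitSpec(seed=1), PrepConfig(k_selected=3))
        avg = grid.region_average_auc("c1")
        assert avg.min() > 60.0  # every region carries the same injected signal

    def test_misaligned_region_index_rejected(self, rng):
        tables = region_tables(rng)
        bad = tables["full"].copy()
        bad.index = pd.Index([f"T{i:03d}" for i in range(len(bad))], name="subject_id")
        tables["full"] = bad
        with pytest.raises(AlignmentError):
            run_grid({"c1": tables}, FAST_SPECS, SplitSpec(), PrepConfig(k_selected=3))

    def test_classifier_average_formula(self):
        # fabricated per-region AUCs: cores average 80.7, peripheries 79.3
        cells = {}
        aucs = {
            "core25": 80.7, "core50": 80.7, "core75": 80.7,
            "periphery25": 79.3, "periphery50": 79.3, "periphery75": 79.3,
            "full": 99.0,  # excluded from the core/periphery average
        }
        for region, auc in aucs.items():
            report = MetricsReport(
                acc=0, sen=0, spe=0, auc=auc,
                acc_half_width=0, sen_half_width=0, spe_half_width=0, auc_half_width=0,
                mcc=0, f1=0, mcnemar_p=1, chi2_p=1,
            )
            cells[("c", region, "CatBoost")] = GridCell("c", region, "CatBoost", report, None, None)
        grid = ExperimentGrid(cells, {}, {}, SplitSpec())
        assert grid.classifier_average_auc("c")["CatBoost"] == pytest.approx(80.0)


class TestExternalValidation:
    def test_same_cohort_reduces_to_resubstitution(self, rng):
        tables = region_tables(rng, regions=("full",))
        out = external_validate(tables, tables, FAST_SPECS, PrepConfig(k_selected=3))
        assert set(out) == {("full", s.name) for s in FAST_SPECS}
        assert out[("full", "RF")].report.acc > 80.0

    def test_swapping_cohorts_changes_results(self, rng):
        a = region_tables(rng, n=40, regions=("full",))
        b = region_tables(rng, n=40, regions=("full",))
        ab = external_validate(a, b, FAST_SPECS[:2], PrepConfig(k_selected=3))
        ba = external_validate(b, a, FAST_SPECS[:2], PrepConfig(k_selected=3))
        assert not np.array_equal(ab[("full", "RF")].scores, ba[("full", "RF")].scores)

    def test_same_distribution_external_close_to_internal(self, rng):
        a = region_tables(rng, n=80, regions=("full",))
        b = region_tables(rng, n=80, regions=("full",))
        out = external_validate(a, b, [ModelSpec("RF", {"n_estimators": 51})], PrepConfig(k_selected=3))
        assert out[("full", "RF")].report.auc > 75.0

    def test_mismatched_features_rejected(self, rng):
        a = region_tables(rng, regions=("full",))
        b = {"full": a["full"].rename(columns={"f0": "g0"})}
        with pytest.raises(AlignmentError):
            external_validate(a, b, FAST_SPECS[:1], PrepConfig(k_selected=3))
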