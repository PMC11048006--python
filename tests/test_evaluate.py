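"""Diagnostic metrics, paired tests, biopsy comparison, clinical statistics."""

import numpy as np
import pytest

from subgrade.evaluate import (
    BiopsyRecord,
    ConfusionMatrix,
    biopsy_compare,
    chi2_randomness_p,
    clinical_stats,
    confusion,
    mcnemar_p,
    metrics,
)
from subgrade.phantoms import COHORT1_CLINICAL, generate_cohort


class TestConfusion:
    def test_enumerated_example(self):
        cm = confusion([1, 0, 1], [1, 1, 0])
        assert (cm.TP, cm.FP, cm.FN, cm.TN) == (1, 1, 1, 0)

    def test_perfect_and_degenerate_predictors(self):
        perfect = confusion([1, 0, 1], [1, 0, 1])
        assert perfect.FP == perfect.FN == 0
        allneg = confusion([1, 0, 1], [0, 0, 0])
        assert allneg.TP == allneg.FP == 0

    def test_empty_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])
        with pytest.raises(ValueError):
            confusion([1, 2], [0, 1])


class TestMetrics:
    def test_all_correct(self):
        r = metrics(ConfusionMatrix(TP=5, FP=0, TN=5, FN=0))
        assert r.mcc == 1.0
        assert r.f1 == 1.0
        assert r.auc == 100.0

    def test_trapezoidal_auc_with_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.6, 0.4, 0.8])
        r = metrics(confusion(y, (scores >= 0.5).astype(int)), scores=scores, y_true=y)
        assert r.auc == pytest.approx(75.0)

    def test_mcc_invariant_f1_not_under_class_swap(self):
        y_true = np.array([1, 1, 1, 0, 0, 1, 0, 1, 0, 0, 0])
        y_pred = np.array([1, 0, 1, 0, 1, 1, 0, 0, 0, 1, 0])
        r = metrics(confusion(y_true, y_pred))
        r_swapped = metrics(confusion(1 - y_true, 1 - y_pred))
        assert r.mcc == pytest.approx(r_swapped.mcc)
        assert r.f1 != pytest.approx(r_swapped.f1)

    def test_mcc_sign_follows_diagonal(self):
        good = metrics(ConfusionMatrix(TP=8, FP=2, TN=7, FN=3))
        bad = metrics(ConfusionMatrix(TP=2, FP=8, TN=3, FN=7))
        assert good.mcc > 0 > bad.mcc

    def test_zero_factor_mcc_flagged(self):
        r = metrics(ConfusionMatrix(TP=0, FP=0, TN=5, FN=5))
        assert r.mcc == 0.0
        assert "mcc_zero_factor" in r.flags

    def test_acc_between_sen_spe_extremes(self):
        r = metrics(ConfusionMatrix(TP=9, FP=4, TN=13, FN=2))
        assert min(r.sen, r.spe) <= r.acc <= max(r.sen, r.spe)


class TestMcNemar:
    def test_symmetric_errors_give_p_one(self):
        assert mcnemar_p(ConfusionMatrix(TP=3, FP=4, TN=3, FN=4)) == 1.0
        assert mcnemar_p(ConfusionMatrix(TP=5, FP=0, TN=5, FN=0)) == 1.0

    def test_monotone_in_asymmetry(self):
        ps = [
            mcnemar_p(ConfusionMatrix(TP=1, FP=fp, TN=1, FN=10))
            for fp in (10, 6, 3, 0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_single_discordant_pair(self):
        assert mcnemar_p(ConfusionMatrix(TP=10, FP=0, TN=17, FN=1)) == pytest.approx(
            0.3173, abs=1e-4
        )


class TestChi2Randomness:
    def test_strong_association_significant(self):
        p = chi2_randomness_p(ConfusionMatrix(TP=20, FP=0, TN=20, FN=0))
        assert p < 1e-6

    def test_uniform_mode_even_split(self):
        p = chi2_randomness_p(
            ConfusionMatrix(TP=5, FP=5, TN=5, FN=5), mode="goodness_of_fit_uniform"
        )
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        p = chi2_randomness_p(ConfusionMatrix(TP=1, FP=8, TN=9, FN=10))
        assert p == pytest.approx(0.0356, abs=2e-3)


class TestBiopsyCompare:
    def _records(self):
        # 3 high-grade, 3 low-grade by nephrectomy; one indeterminate biopsy
        return [
            BiopsyRecord("s1", "high", "high"),
            BiopsyRecord("s2", "indeterminate", "high"),  # counts as low -> FN
            BiopsyRecord("s3", "low", "high"),
            BiopsyRecord("s4", "low", "low"),
            BiopsyRecord("s5", "indeterminate", "low"),  # counts as high -> FP
            BiopsyRecord("s6", "low", "low"),
        ]

    def test_indeterminate_resolves_against_biopsy(self):
        records = self._records()
        ml = {r.subject_id: {"high": 1, "low": 0}[r.nephrectomy_grade] for r in records}
        biopsy_rep, ml_rep = biopsy_compare(records, ml)
        assert biopsy_rep.cm.FN == 2  # s2 indeterminate + s3 wrong
        assert biopsy_rep.cm.FP == 1  # s5 indeterminate
        assert ml_rep.acc == 100.0

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError):
            biopsy_compare(self._records(), {"s1": 1})

    def test_pure_function_rerun_stable(self):
        records = self._records()
        ml = {r.subject_id: 1 for r in records}
        a = biopsy_compare(records, ml)
        b = biopsy_compare(records, ml)
        assert a[0].as_dict() == b[0].as_dict()
        assert a[1].as_dict() == b[1].as_dict()

    def test_reference_grade_validated(self):
        with pytest.raises(ValueError):
            BiopsyRecord("s1", "high", "indeterminate")


class TestClinicalStats:
    def test_identical_groups_not_significant(self, rng):
        import pandas as pd

        x = rng.normal(60, 10, size=40)
        table = pd.DataFrame(
            {
                "grade_label": np.repeat([0, 1], 40),
                "age_years": np.concatenate([x, x]),
                "tumour_size_cm": np.concatenate([x / 10, x / 10]),
                "tumour_volume_cm3": np.concatenate([x, x]),
                "sex": ["male", "female"] * 40,
            }
        )
        stats_table = clinical_stats(table)
        t_rows = stats_table[stats_table.test == "t-test"]
        assert (t_rows.p_value > 0.95).all()

    def test_point_biserial_of_median_threshold_is_large(self, rng):
        import pandas as pd

        x = rng.normal(5, 2, size=200)
        table = pd.DataFrame(
            {
                "grade_label": (x > np.median(x)).astype(int),
                "age_years": np.clip(x * 10 + 10, 18, 100),
                "tumour_size_cm": x - x.min() + 0.5,
                "tumour_volume_cm3": x - x.min() + 0.5,
                "sex": ["male"] * 100 + ["female"] * 100,
            }
        )
        stats_table = clinical_stats(table)
        row = stats_table[stats_table.variable == "tumour_size_cm"].iloc[0]
        assert row.rpb > 0.7
        assert row.significant

    def test_published_size_effect_detected_across_seeds(self):
        # power check: at n=187 with the published per-class size parameters
        # the size difference should be detected in essentially every draw
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            table, _ = generate_cohort(187, clinical_params=COHORT1_CLINICAL, seed=seed)
            st = clinical_stats(table)
            row = st[st.variable == "tumour_size_cm"].iloc[0]
            hits += bool(row.significant)
        assert hits >= n_seeds - 1

    def test_single_class_rejected(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "grade_label": [1, 1, 1],
                "age_years": [50.0, 60.0, 70.0],
                "tumour_size_cm": [3.0, 4.0, 5.0],
                "tumour_volume_cm3": [20.0, 30.0, 40.0],
                "sex": ["male", "female", "male"],
            }
        )
        with pytest.raises(ValueError):
            clinical_stats(table)
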