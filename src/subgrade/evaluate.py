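"""Confusion-matrix metrics, paired tests, clinical statistics, and the
biopsy-vs-ML comparison harness.

Conventions: the positive class is 1 = high-grade throughout.  Percentages
(ACC/SEN/SPE/AUC) are reported on the 0-100 scale with Wald 95% half-widths
(1.96 * sqrt(p(1-p)/m)), where the denominator m is the total count for ACC
and AUC, the positives for SEN, and the negatives for SPE.  MCC and F1 are
unitless.  McNemar's test is the chi-squared form (FN-FP)^2/(FN+FP) on 1 df
without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

Z95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "BiopsyRecord",
    "confusion",
    "metrics",
    "mcnemar_p",
    "chi2_randomness_p",
    "biopsy_compare",
    "clinical_stats",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive = high-grade."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1D of equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _wald_half_width(p: float, m: int) -> float:
    """Wald 95% half-width on the percentage scale; 0 when m == 0."""
    if m == 0:
        return 0.0
    return 100.0 * Z95 * np.sqrt(p * (1.0 - p) / m)


@dataclass
class MetricsReport:
    """The full diagnostic metric panel for one predictor."""

    acc: float
    sen: float
    spe: float
    auc: float
    acc_half_width: float
    sen_half_width: float
    spe_half_width: float
    auc_half_width: float
    mcc: float
    f1: float
    mcnemar_p: float
    chi2_p: float
    cm: ConfusionMatrix | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "SPE": self.spe,
            "SEN": self.sen,
            "AUC": self.auc,
            "MCC": self.mcc,
            "F1": self.f1,
            "McN": self.mcnemar_p,
            "chi2": self.chi2_p,
        }


def mcnemar_p(cm: ConfusionMatrix) -> float:
    """McNemar's test on the discordant error counts, no continuity correction."""
    discordant = cm.FN + cm.FP
    if discordant == 0:
        return 1.0
    chi2 = (cm.FN - cm.FP) ** 2 / discordant
    return float(stats.chi2.sf(chi2, df=1))


def chi2_randomness_p(cm: ConfusionMatrix, mode: str = "independence") -> float:
    """Chi-squared test of the predictions against randomness.

    ``independence``: 2x2 test of prediction vs truth (no continuity
    correction, 1 df).  ``goodness_of_fit_uniform``: predicted label counts
    against a 50/50 split.
    """
    if mode == "independence":
        table = np.array([[cm.TP, cm.FN], [cm.FP, cm.TN]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 1.0  # a margin is empty; association undefined
        result = stats.chi2_contingency(table, correction=False)
        return float(result.pvalue)
    if mode == "goodness_of_fit_uniform":
        pred_pos = cm.TP + cm.FP
        pred_neg = cm.TN + cm.FN
        res = stats.chisquare([pred_pos, pred_neg])
        return float(res.pvalue)
    raise ValueError(f"unknown mode: {mode}")


def metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
    chi2_mode: str = "independence",
) -> MetricsReport:
    """Compute the full metric panel from a confusion matrix.

    With per-sample ``scores`` (and matching ``y_true``) the AUC is the
    trapezoidal ROC area; for label-only predictors it is the balanced
    accuracy (SEN + SPE)/2 — the ROC area of a single-threshold classifier.
    """
    flags: list[str] = []
    n = cm.n
    acc = (cm.TP + cm.TN) / n
    sen = cm.TP / cm.positives if cm.positives else 0.0
    spe = cm.TN / cm.negatives if cm.negatives else 0.0

    if scores is not None:
        if y_true is None:
            raise ValueError("scores require matching y_true")
        auc = float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))
    else:
        auc = (sen + spe) / 2.0

    denom_factors = (
        (cm.TP + cm.FP),
        (cm.TP + cm.FN),
        (cm.TN + cm.FP),
        (cm.TN + cm.FN),
    )
    if 0 in denom_factors:
        mcc = 0.0
        flags.append("mcc_zero_factor")
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / np.sqrt(
            float(np.prod([float(f) for f in denom_factors]))
        )

    f1_denom = 2 * cm.TP + cm.FP + cm.FN
    f1 = 2 * cm.TP / f1_denom if f1_denom else 0.0

    return MetricsReport(
        acc=100.0 * acc,
        sen=100.0 * sen,
        spe=100.0 * spe,
        auc=100.0 * auc,
        acc_half_width=_wald_half_width(acc, n),
        sen_half_width=_wald_half_width(sen, cm.positives),
        spe_half_width=_wald_half_width(spe, cm.negatives),
        auc_half_width=_wald_half_width(auc, n),
        mcc=float(mcc),
        f1=float(f1),
        mcnemar_p=mcnemar_p(cm),
        chi2_p=chi2_randomness_p(cm, chi2_mode),
        cm=cm,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Biopsy-vs-ML comparison


@dataclass(frozen=True)
class BiopsyRecord:
    """One subject with both biopsy and nephrectomy (reference) grading."""

    subject_id: str
    biopsy_grade: str  # {"low", "high", "indeterminate"}
    nephrectomy_grade: str  # {"low", "high"}

    def __post_init__(self) -> None:
        if self.biopsy_grade not in ("low", "high", "indeterminate"):
            raise ValueError(f"bad biopsy grade: {self.biopsy_grade}")
        if self.nephrectomy_grade not in ("low", "high"):
            raise ValueError(
                f"nephrectomy (reference) grade missing or invalid: "
                f"{self.nephrectomy_grade!r}"
            )


def biopsy_compare(
    records: list[BiopsyRecord],
    ml_predictions: dict[str, int],
    ml_scores: dict[str, float] | None = None,
) -> tuple[MetricsReport, MetricsReport]:
    """Score biopsy grading and ML predictions against nephrectomy histology.

    An indeterminate biopsy is resolved to the *opposite* of the nephrectomy
    grade before scoring (it contributed no usable decision, so it counts as
    an error).  Returns (biopsy_report, ml_report) on the same subjects.
    """
    missing = [r.subject_id for r in records if r.subject_id not in ml_predictions]
    if missing:
        raise ValueError(f"ML predictions missing for subjects: {missing}")
    to_int = {"low": 0, "high": 1}
    y_true = np.array([to_int[r.nephrectomy_grade] for r in records])
    biopsy_pred = np.array(
        [
            1 - to_int[r.nephrectomy_grade]
            if r.biopsy_grade == "indeterminate"
            else to_int[r.biopsy_grade]
            for r in records
        ]
    )
    ml_pred = np.array([int(ml_predictions[r.subject_id]) for r in records])
    biopsy_report = metrics(confusion(y_true, biopsy_pred))
    if ml_scores is not None:
        scores = np.array([float(ml_scores[r.subject_id]) for r in records])
        ml_report = metrics(confusion(y_true, ml_pred), scores=scores, y_true=y_true)
    else:
        ml_report = metrics(confusion(y_true, ml_pred))
    return biopsy_report, ml_report


# ---------------------------------------------------------------------------
# Clinical covariate statistics


def clinical_stats(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable association tests of clinical covariates with grade.

    Continuous covariates (age, size, volume): Welch-free two-sample
    Student's t-test plus the point-biserial correlation with grade;
    sex: chi-squared test on the 2x2 contingency table.  Significance at
    p < 0.05.
    """
    y = cohort_table["grade_label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("clinical statistics need both grade classes present")
    rows = []
    for col in ("age_years", "tumour_size_cm", "tumour_volume_cm3"):
        x = cohort_table[col].to_numpy(dtype=float)
        t_res = stats.ttest_ind(x[y == 1], x[y == 0])
        rpb = stats.pointbiserialr(y, x)
        rows.append(
            {
                "variable": col,
                "test": "t-test",
                "statistic": float(t_res.statistic),
                "p_value": float(t_res.pvalue),
                "rpb": float(rpb.statistic),
                "significant": bool(t_res.pvalue < 0.05),
            }
        )
    table = pd.crosstab(cohort_table["sex"], cohort_table["grade_label"])
    chi2_res = stats.chi2_contingency(table)
    rows.append(
        {
            "variable": "sex",
            "test": "chi2",
            "statistic": float(chi2_res.statistic),
            "p_value": float(chi2_res.pvalue),
            "rpb": np.nan,
            "significant": bool(chi2_res.pvalue < 0.05),
        }
    )
    return pd.DataFrame(rows)
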