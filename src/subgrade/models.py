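"""The 11-classifier zoo and the cohort x region x model experiment grid.

Default hyperparameters are the published tuned settings, honoured verbatim
(including deliberately tiny iteration caps such as MLP ``max_iter=5`` and
LR ``max_iter=4``, whose convergence warnings are expected and non-fatal).
The "CatBoost" slot is a 50-iteration gradient-boosting classifier from
scikit-learn — the boosting settings are honoured, the ordered-boosting
variant is not available here.  The LSTM is the in-package NumPy
implementation and is excluded from the default grid (it is orders of
magnitude slower than the rest of the zoo for no measurable benefit on
tabular features); pass ``model_names(include_lstm=True)`` to add it.

One stratified 67/33 split is drawn per cohort and reused for every
region and classifier, so all 77 cells of a cohort score the same held-out
subjects.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .evaluate import MetricsReport, confusion, metrics
from .lstm import LSTMClassifier
from .prep import (
    ScalerParams,
    SelectionReport,
    correlation_filter,
    importance_select,
    smote,
    zscore_apply,
    zscore_fit,
)
from .subregions import AlignmentError

MODEL_NAMES = (
    "SVM",
    "RF",
    "XGBoost",
    "NB",
    "MLP",
    "LSTM",
    "LR",
    "QDA",
    "LightGBM",
    "CatBoost",
    "AdaBoost",
)

CORE_REGIONS = ("core25", "core50", "core75")
PERIPHERY_REGIONS = ("periphery25", "periphery50", "periphery75")
ALL_REGIONS = ("full",) + CORE_REGIONS + PERIPHERY_REGIONS

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"kernel": "rbf", "probability": True, "random_state": 42, "gamma": 0.2, "C": 0.01},
    "RF": {"n_estimators": 401, "random_state": 42, "max_depth": 3},
    "XGBoost": {"random_state": 42, "learning_rate": 0.01, "n_estimators": 401, "gamma": 0.52},
    "NB": {},
    "MLP": {
        "hidden_layer_sizes": (401, 201),
        "activation": "relu",
        "solver": "adam",
        "max_iter": 5,
    },
    "LSTM": {
        "learning_rate": 0.01,
        "epochs": 1000,
        "batch_size": 16,
        "hidden_size": 16,
        "random_state": 42,
    },
    "LR": {"random_state": 42, "max_iter": 4},
    "QDA": {"reg_param": 0.05},
    "LightGBM": {"random_state": 42, "n_estimators": 9},
    "CatBoost": {"random_state": 42, "n_estimators": 50},
    "AdaBoost": {
        "base_estimator": "rf",
        "n_estimators": 201,
        "learning_rate": 0.01,
        "random_state": 42,
    },
}


class ModelConfigError(ValueError):
    """Raised for an unknown classifier name."""


class _OrientedSVC(SVC):
    """SVC whose probability scale is re-oriented against the training labels.

    With a heavily regularised margin (C = 0.01) the decision values are
    tiny and the internal Platt calibration can fit an *inverted* sigmoid on
    small training sets, making ``predict_proba`` disagree with the SVM's
    own decision rule.  After fitting, the training ROC of the calibrated
    probabilities is checked; when it is below chance the probability scale
    is flipped so scores rank consistently with the margin classifier.
    """

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight=sample_weight)
        from sklearn.metrics import roc_auc_score

        p = super().predict_proba(X)[:, 1]
        self.flip_proba_ = bool(roc_auc_score(y, p) < 0.5)
        return self

    def predict_proba(self, X):
        p = super().predict_proba(X)
        if getattr(self, "flip_proba_", False):
            p = p[:, ::-1]
        return p


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier with (possibly overridden) hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ModelConfigError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )

    def resolved(self) -> dict:
        hp = copy.deepcopy(DEFAULT_HYPERPARAMETERS[self.name])
        hp.update(self.hyperparameters)
        return hp


def model_names(include_lstm: bool = False) -> tuple[str, ...]:
    if include_lstm:
        return MODEL_NAMES
    return tuple(n for n in MODEL_NAMES if n != "LSTM")


def default_specs(include_lstm: bool = False) -> list[ModelSpec]:
    return [ModelSpec(name) for name in model_names(include_lstm)]


def scaled_down_specs(include_lstm: bool = False) -> list[ModelSpec]:
    """Specs with the heavy ensembles shrunk for single-CPU batch runs.

    Only sizes change (AdaBoost forest and round counts, LSTM epochs);
    learning rates, depths and seeds stay at their defaults.
    """
    overrides: dict[str, dict] = {
        "AdaBoost": {"n_estimators": 15, "rf_n_estimators": 25},
        "LSTM": {"epochs": 60},
    }
    return [
        ModelSpec(name, overrides.get(name, {})) for name in model_names(include_lstm)
    ]


def build_estimator(spec: ModelSpec):
    """Instantiate the (unfitted) scikit-learn-compatible estimator."""
    hp = spec.resolved()
    name = spec.name
    if name == "SVM":
        return _OrientedSVC(**hp)
    if name == "RF":
        return RandomForestClassifier(**hp)
    if name == "XGBoost":
        return XGBClassifier(eval_metric="logloss", verbosity=0, **hp)
    if name == "NB":
        return GaussianNB(**hp)
    if name == "MLP":
        return MLPClassifier(random_state=spec.seed, **hp)
    if name == "LSTM":
        return LSTMClassifier(**hp)
    if name == "LR":
        return LogisticRegression(**hp)
    if name == "QDA":
        return QuadraticDiscriminantAnalysis(**hp)
    if name == "LightGBM":
        return LGBMClassifier(verbose=-1, **hp)
    if name == "CatBoost":
        return GradientBoostingClassifier(**hp)
    if name == "AdaBoost":
        hp = dict(hp)
        base_kind = hp.pop("base_estimator", "rf")
        rf_n = hp.pop("rf_n_estimators", DEFAULT_HYPERPARAMETERS["RF"]["n_estimators"])
        if base_kind != "rf":
            raise ModelConfigError(f"unsupported AdaBoost base: {base_kind}")
        base = RandomForestClassifier(
            n_estimators=rf_n,
            max_depth=DEFAULT_HYPERPARAMETERS["RF"]["max_depth"],
            random_state=42,
        )
        return AdaBoostClassifier(estimator=base, **hp)
    raise ModelConfigError(name)  # pragma: no cover


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit one classifier; labels must be binary {0, 1}."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all() or len(np.unique(y)) != 2:
        raise ValueError("y must contain both binary labels 0 (low) and 1 (high)")
    model = build_estimator(spec)
    with warnings.catch_warnings():
        # tiny published iteration caps trip convergence warnings by design
        warnings.filterwarnings("ignore", message=".*onverge.*")
        model.fit(np.asarray(X, dtype=np.float64), y)
    return model


def predict(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores in [0, 1] and their 0.5-threshold labels."""
    scores = model.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]
    return (scores >= 0.5).astype(int), scores


# ---------------------------------------------------------------------------
# Region preparation (standardise -> filter -> select -> balance)


@dataclass(frozen=True)
class PrepConfig:
    threshold_r: float = 0.8
    k_selected: int = 30
    smote_k: int = 5
    seed: int = 42


@dataclass
class PreparedRegion:
    """Training/test matrices after the leakage-safe preparation chain."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    scaler: ScalerParams
    selection: SelectionReport


def feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"subject_id", "grade_label", "region", "cohort"}
    return [c for c in table.columns if c not in meta]


def prepare_region(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    prep: PrepConfig = PrepConfig(),
) -> PreparedRegion:
    """Run the full preparation chain, fitted on the training rows only."""
    cols = feature_columns(train_table)
    if cols != feature_columns(test_table):
        raise AlignmentError("train/test feature columns differ")
    y_train = train_table["grade_label"].to_numpy(dtype=int)
    scaler = zscore_fit(train_table[cols])
    x_train = zscore_apply(scaler, train_table[cols])
    x_test = zscore_apply(scaler, test_table[cols])
    report = correlation_filter(x_train, prep.threshold_r)
    x_train = x_train[report.kept]
    report = importance_select(
        x_train, y_train, k=prep.k_selected, seed=prep.seed, report=report
    )
    x_train = x_train[report.kept]
    x_test = x_test[report.kept]
    xb, yb = smote(x_train.to_numpy(), y_train, prep.smote_k, prep.seed)
    return PreparedRegion(
        X_train=xb,
        y_train=yb,
        X_test=x_test.to_numpy(),
        scaler=scaler,
        selection=report,
    )


# ---------------------------------------------------------------------------
# The experiment grid


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.67
    stratified: bool = True
    seed: int = 42


@dataclass
class GridCell:
    cohort: str
    region: str
    model: str
    report: MetricsReport
    y_pred: np.ndarray
    scores: np.ndarray


@dataclass
class ExperimentGrid:
    """All fitted cells plus the per-cohort split bookkeeping."""

    cells: dict[tuple[str, str, str], GridCell]
    train_index: dict[str, np.ndarray]
    test_index: dict[str, np.ndarray]
    split_spec: SplitSpec
    prepared: dict[tuple[str, str], PreparedRegion] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def auc_table(self) -> pd.DataFrame:
        rows = [
            {
                "cohort": c.cohort,
                "region": c.region,
                "model": c.model,
                "auc": c.report.auc,
            }
            for c in self.cells.values()
        ]
        return pd.DataFrame(rows)

    def region_average_auc(self, cohort: str) -> pd.Series:
        """Mean test AUC per region, averaged over the classifier zoo."""
        t = self.auc_table()
        t = t[t.cohort == cohort]
        return t.groupby("region")["auc"].mean().sort_values(ascending=False)

    def classifier_average_auc(self, cohort: str) -> pd.Series:
        """Per classifier: (mean AUC over cores + mean AUC over peripheries) / 2."""
        t = self.auc_table()
        t = t[t.cohort == cohort]
        cores = (
            t[t.region.isin(CORE_REGIONS)].groupby("model")["auc"].mean()
        )
        peris = (
            t[t.region.isin(PERIPHERY_REGIONS)].groupby("model")["auc"].mean()
        )
        return ((cores + peris) / 2.0).sort_values(ascending=False)


def _split_cohort(
    tables: dict[str, pd.DataFrame], split: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    ref_region = next(iter(tables))
    ref = tables[ref_region]
    for region, t in tables.items():
        if not t.index.equals(ref.index):
            raise AlignmentError(
                f"region {region!r} subject index differs from {ref_region!r}"
            )
    y = ref["grade_label"].to_numpy(dtype=int)
    idx = np.arange(len(ref))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=split.train_fraction,
        stratify=y if split.stratified else None,
        random_state=split.seed,
    )
    return np.sort(train_idx), np.sort(test_idx)


def run_grid(
    cohort_tables: dict[str, dict[str, pd.DataFrame]],
    specs: list[ModelSpec] | None = None,
    split_spec: SplitSpec = SplitSpec(),
    prep: PrepConfig = PrepConfig(),
) -> ExperimentGrid:
    """Train and score every cohort x region x classifier cell.

    Per cohort a single stratified split is drawn and reused across all
    regions and classifiers; each region runs the leakage-safe preparation
    chain once, then every classifier is fitted on the same balanced
    training matrix.
    """
    if specs is None:
        specs = default_specs()
    cells: dict[tuple[str, str, str], GridCell] = {}
    train_index: dict[str, np.ndarray] = {}
    test_index: dict[str, np.ndarray] = {}
    prepared: dict[tuple[str, str], PreparedRegion] = {}
    for cohort, tables in cohort_tables.items():
        tr_idx, te_idx = _split_cohort(tables, split_spec)
        train_index[cohort] = tr_idx
        test_index[cohort] = te_idx
        for region, table in tables.items():
            train_table = table.iloc[tr_idx]
            test_table = table.iloc[te_idx]
            pr = prepare_region(train_table, test_table, prep)
            prepared[(cohort, region)] = pr
            y_test = test_table["grade_label"].to_numpy(dtype=int)
            for spec in specs:
                model = train_model(spec, pr.X_train, pr.y_train)
                y_pred, scores = predict(model, pr.X_test)
                report = metrics(confusion(y_test, y_pred), scores=scores, y_true=y_test)
                cells[(cohort, region, spec.name)] = GridCell(
                    cohort=cohort,
                    region=region,
                    model=spec.name,
                    report=report,
                    y_pred=y_pred,
                    scores=scores,
                )
    return ExperimentGrid(
        cells=cells,
        train_index=train_index,
        test_index=test_index,
        split_spec=split_spec,
        prepared=prepared,
    )


def external_validate(
    train_tables: dict[str, pd.DataFrame],
    test_tables: dict[str, pd.DataFrame],
    specs: list[ModelSpec] | None = None,
    prep: PrepConfig = PrepConfig(),
) -> dict[tuple[str, str], GridCell]:
    """Train on one whole cohort, score another: scaler, selection, SMOTE and
    models all fit on the training cohort only."""
    if specs is None:
        specs = default_specs()
    if set(train_tables) != set(test_tables):
        raise AlignmentError("train and test cohorts expose different regions")
    out: dict[tuple[str, str], GridCell] = {}
    for region in train_tables:
        pr = prepare_region(train_tables[region], test_tables[region], prep)
        y_test = test_tables[region]["grade_label"].to_numpy(dtype=int)
        for spec in specs:
            model = train_model(spec, pr.X_train, pr.y_train)
            y_pred, scores = predict(model, pr.X_test)
            report = metrics(confusion(y_test, y_pred), scores=scores, y_true=y_test)
            out[(region, spec.name)] = GridCell(
                cohort="external",
                region=region,
                model=spec.name,
                report=report,
                y_pred=y_pred,
                scores=scores,
            )
    return out
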