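"""Feature standardisation, redundancy filtering, importance selection, SMOTE.

Everything here is fitted on the *training partition only* — each operation
accepts solely the training table, so test-set statistics cannot leak into
scaler parameters, the correlation filter, the importance ranking or the
oversampler by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

__all__ = [
    "ScalerParams",
    "SelectionReport",
    "zscore_fit",
    "zscore_apply",
    "pearson_r",
    "correlation_filter",
    "importance_select",
    "smote",
    "ConstantInputError",
    "BalancingError",
]


class ConstantInputError(ValueError):
    """Raised when a correlation is requested on a constant vector."""


class BalancingError(ValueError):
    """Raised when the minority class is too small to oversample."""


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training mean and standard deviation for z-scoring.

    ``population_sd`` selects the n-denominator convention (default); set
    False for the (n-1) sample convention.  Features constant on the
    training set keep sd 0 and are listed in ``constant_features``; they
    transform to 0 everywhere.
    """

    mean: pd.Series
    sd: pd.Series
    population_sd: bool = True

    @property
    def constant_features(self) -> list[str]:
        return list(self.sd.index[self.sd == 0])

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "mean": self.mean.to_dict(),
                "sd": self.sd.to_dict(),
                "population_sd": self.population_sd,
                "constant_features": self.constant_features,
            },
            indent=2,
        )


def zscore_fit(train_table: pd.DataFrame, population_sd: bool = True) -> ScalerParams:
    if train_table.empty:
        raise ValueError("cannot fit a scaler on an empty table")
    ddof = 0 if population_sd else 1
    return ScalerParams(
        mean=train_table.mean(),
        sd=train_table.std(ddof=ddof),
        population_sd=population_sd,
    )


def zscore_apply(params: ScalerParams, table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != list(params.mean.index):
        raise ValueError("table columns do not match fitted scaler features")
    sd = params.sd.replace(0.0, 1.0)  # constant features map to 0, not inf
    out = (table - params.mean) / sd
    out.loc[:, params.sd == 0.0] = 0.0
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


@dataclass
class SelectionReport:
    """Outcome of the redundancy filter and/or the importance ranking."""

    threshold_r: float
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    kept_by_importance: list[tuple[str, float]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    k_selected: int | None = None

    @property
    def dropped_names(self) -> set[str]:
        return {f for f, _, _ in self.dropped_by_correlation}

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "threshold_r": None if np.isnan(self.threshold_r) else self.threshold_r,
                "dropped_by_correlation": [
                    {"feature": f, "partner": p, "r": r}
                    for f, p, r in self.dropped_by_correlation
                ],
                "kept_by_importance": [
                    {"feature": f, "importance": imp}
                    for f, imp in self.kept_by_importance
                ],
                "kept": self.kept,
                "k_selected": self.k_selected,
            },
            indent=2,
        )


def correlation_filter(
    train_table: pd.DataFrame, threshold: float = 0.8
) -> SelectionReport:
    """Greedy pairwise-correlation filter in canonical (column) order.

    Features are scanned in column order; a feature is dropped when its
    absolute Pearson correlation with any earlier *kept* feature exceeds the
    threshold (the later-ordered member of an offending pair loses).  The
    surviving set therefore has all pairwise |r| <= threshold on the
    training data, deterministically.
    """
    cols = list(train_table.columns)
    if len(cols) < 2:
        raise ValueError("correlation filter needs at least 2 features")
    x = train_table.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)  # constant features correlate with nothing
    report = SelectionReport(threshold_r=threshold)
    kept_idx: list[int] = []
    for j, name in enumerate(cols):
        partner = None
        for i in kept_idx:
            if abs(r[i, j]) > threshold:
                partner = i
                break
        if partner is None:
            kept_idx.append(j)
            report.kept.append(name)
        else:
            report.dropped_by_correlation.append(
                (name, cols[partner], float(r[partner, j]))
            )
    return report


def importance_select(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    k: int = 30,
    seed: int = 42,
    n_estimators: int = 100,
    report: SelectionReport | None = None,
) -> SelectionReport:
    """Rank features by gradient-boosted-tree gain importance and keep the top k.

    Fitted on training rows only.  ``k`` larger than the available feature
    count is clamped with a warning.  When a ``report`` from the correlation
    filter is passed, the ranking is recorded into it (and the kept set
    replaced); otherwise a fresh report is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_features = train_X.shape[1]
    if k > n_features:
        warnings.warn(
            f"k={k} exceeds {n_features} available features; clamping", stacklevel=2
        )
        k = n_features
    model = XGBClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        importance_type="gain",
        verbosity=0,
        eval_metric="logloss",
    )
    model.fit(train_X.to_numpy(dtype=np.float64), np.asarray(train_y))
    gains = model.feature_importances_.astype(np.float64)
    cols = list(train_X.columns)
    # stable ranking: gain descending, canonical order breaking ties
    order = sorted(range(n_features), key=lambda j: (-gains[j], j))
    ranked = [(cols[j], float(gains[j])) for j in order]
    if report is None:
        report = SelectionReport(threshold_r=np.nan)
    report.kept_by_importance = ranked[:k]
    report.kept = [f for f, _ in ranked[:k]]
    report.k_selected = k
    return report


def smote(
    train_X: np.ndarray,
    train_y: np.ndarray,
    k_neighbours: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling on the training partition.

    Each synthetic sample is ``x_i + lambda * (x_nn - x_i)`` with ``x_nn``
    one of the k nearest minority neighbours of a random minority sample
    ``x_i`` (Euclidean metric) and ``lambda ~ U(0, 1)``, so synthetic points
    lie on segments between same-class originals.  Originals are preserved;
    the minority class is raised to the majority count.
    """
    X = np.asarray(train_X, dtype=np.float64)
    y = np.asarray(train_y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE expects binary labels, got classes {classes}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise BalancingError("minority class needs at least 2 samples")
    if k_neighbours > n_min - 1:
        warnings.warn(
            f"k_neighbours={k_neighbours} clamped to {n_min - 1}", stacklevel=2
        )
        k_neighbours = n_min - 1

    Xm = X[y == minority]
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbours]

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbours, size=n_new)
    lam = rng.random(size=n_new)
    neighbours = Xm[nn[base, pick]]
    synthetic = Xm[base] + lam[:, None] * (neighbours - Xm[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
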