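"""Diagnostic classification from pooled indices, age, and FAB score.

One logistic model per exercise and per problem: binary (MCI vs OA;
binomial logit) and ternary (OA vs SCI vs MCI; single multinomial logit).
Predictors are standardised internally and a small L2 ridge keeps the
coefficients finite under the quasi-separation that leave-one-out folds
of a 44-participant sample invite.  Validation is leave-one-out
cross-validation; performance is summarised through confusion matrices
and the usual small-sample metric suite (sensitivity/specificity/accuracy
for two classes; per-class and support-weighted recall, precision and F1
plus overall accuracy for three).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

CLASS_ORDER = ("OA", "SCI", "MCI")


@dataclass
class ModelSpec:
    predictors: tuple[str, ...] = ("pooled_index", "age", "fab")
    outcome: str = "binary"  # "binary" (MCI vs OA) or "ternary"
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if self.outcome not in ("binary", "ternary"):
            raise ValueError("outcome must be 'binary' or 'ternary'")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    @property
    def classes(self) -> tuple[str, ...]:
        return ("OA", "MCI") if self.outcome == "binary" else CLASS_ORDER


@dataclass
class ClassificationReport:
    spec: ModelSpec
    confusion: pd.DataFrame
    metrics: dict
    y_true: list = field(default_factory=list)
    y_pred: list = field(default_factory=list)


def _make_model(spec: ModelSpec) -> Pipeline:
    c = np.inf if spec.ridge == 0 else 1.0 / spec.ridge
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=c, max_iter=5000, solver="lbfgs")),
        ]
    )


def fit_logistic(X: np.ndarray, y, spec: ModelSpec | None = None) -> Pipeline:
    """Fit the (multinomial) logistic model on standardised predictors."""
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    present = set(np.unique(y))
    missing = [c for c in spec.classes if c not in present]
    if missing or len(present) < 2:
        raise ValueError(f"classes absent from y: {missing or 'all but one'}")
    model = _make_model(spec)
    model.fit(X, y)
    return model


def _predict_ordered(model: Pipeline, X: np.ndarray, classes) -> list[str]:
    """Argmax prediction with deterministic ties broken by class order."""
    proba = model.predict_proba(X)
    fitted = list(model.classes_)
    out = []
    for row in proba:
        best = max(
            (c for c in classes if c in fitted),
            key=lambda c: (row[fitted.index(c)], -classes.index(c)),
        )
        out.append(best)
    return out


def loocv_predict(X: np.ndarray, y, spec: ModelSpec | None = None) -> list[str]:
    """Leave-one-out out-of-sample predictions, one per subject.

    The i-th prediction comes from a model that never saw row i.  Folds
    whose training set loses a whole class still predict among the
    remaining classes, with a warning.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < len(spec.classes) + 2:
        raise ValueError("sample too small for leave-one-out validation")
    preds: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < len(np.unique(y)):
            warnings.warn("a class vanished from a training fold; predicting among the rest")
        model = _make_model(spec)
        model.fit(X[mask], y_train)
        preds.append(_predict_ordered(model, X[i : i + 1], list(spec.classes))[0])
    return preds


def confusion_matrix(y_true, y_pred, classes=CLASS_ORDER) -> pd.DataFrame:
    """Count matrix, rows = true class, columns = predicted class."""
    classes = list(classes)
    unknown = set(y_true) | set(y_pred)
    if not unknown <= set(classes):
        raise ValueError(f"labels outside the class set: {sorted(unknown - set(classes))}")
    m = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        m.loc[t, p] += 1
    return m


def confusion_row_percent(confusion: pd.DataFrame) -> pd.DataFrame:
    """Row-normalised percentages (per true class), as figures report them."""
    sums = confusion.sum(axis=1).replace(0, np.nan)
    return (100.0 * confusion.div(sums, axis=0)).round(0)


def binary_metrics(confusion: pd.DataFrame, positive: str = "MCI") -> dict:
    """Sensitivity, specificity and accuracy (%) of a 2-class confusion."""
    n = int(confusion.to_numpy().sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    neg = [c for c in confusion.index if c != positive][0]
    tp = int(confusion.loc[positive, positive])
    fn = int(confusion.loc[positive, neg])
    tn = int(confusion.loc[neg, neg])
    fp = int(confusion.loc[neg, positive])
    return dict(
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=100.0 * (tp + tn) / n,
    )


def multiclass_metrics(confusion: pd.DataFrame) -> dict:
    """Per-class and support-weighted recall/precision/F1 (%), overall accuracy.

    Weighted averages use true-class supports; a class with no true
    members contributes nothing to them (recall undefined, warned).
    """
    counts = confusion.to_numpy(dtype=float)
    n = counts.sum()
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    diag = np.diag(counts)
    per_class = {}
    for i, cls in enumerate(confusion.index):
        if support[i] == 0:
            warnings.warn(f"class {cls} has no true members; recall undefined")
        recall = 100.0 * diag[i] / support[i] if support[i] else float("nan")
        precision = 100.0 * diag[i] / predicted[i] if predicted[i] else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if np.isfinite(precision) and np.isfinite(recall) and (precision + recall)
            else float("nan")
        )
        per_class[cls] = dict(recall=recall, precision=precision, f1=f1)

    def wavg(key):
        vals = np.array([per_class[c][key] for c in confusion.index])
        m = np.isfinite(vals) & (support > 0)
        return float(np.sum(vals[m] * support[m]) / support[m].sum()) if m.any() else float("nan")
    return dict(
        per_class=per_class,
        weighted_recall=wavg("recall"),
        weighted_precision=wavg("precision"),
        weighted_f1=wavg("f1"),
        overall_accuracy=100.0 * diag.sum() / n if n else float("nan"),
    )


def evaluate_model(
    data: pd.DataFrame, spec: ModelSpec | None = None
) -> ClassificationReport:
    """Leave-one-out evaluation of one model on a prepared frame.

    ``data`` needs a ``group`` column plus every predictor column; rows
    with missing predictors are dropped with a warning.  For the binary
    problem only OA and MCI rows enter.
    """
    spec = spec or ModelSpec()
    d = data.copy()
    if spec.outcome == "binary":
        d = d[d["group"].isin(["OA", "MCI"])]
    keep = d[list(spec.predictors)].notna().all(axis=1)
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} rows with missing predictors")
        d = d[keep]
    X = d[list(spec.predictors)].to_numpy(dtype=float)
    y = d["group"].to_numpy()
    preds = loocv_predict(X, y, spec)
    conf = confusion_matrix(y, preds, classes=list(spec.classes))
    metrics = (
        binary_metrics(conf, positive="MCI")
        if spec.outcome == "binary"
        else multiclass_metrics(conf)
    )
    return ClassificationReport(
        spec=spec, confusion=conf, metrics=metrics, y_true=list(y), y_pred=preds
    )
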