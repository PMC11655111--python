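"""Model families, hyperparameter search, and the evaluation metric suite.

Five interpretable families are tuned and compared: decision tree,
discriminant analysis (linear/quadratic), Gaussian naive Bayes, SVM
(linear/RBF) and k-nearest neighbours.  Hyperparameters are chosen by
seeded random search over the documented spaces, each candidate scored by
subject-grouped 5-fold cross-validated accuracy on the (balanced) training
split, then refit on all training rows.  Performance is reported as
sensitivity, specificity, PPV, NPV and accuracy, each mean +/- SD over
re-balanced evaluation repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import GroupKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("decision_tree", "discriminant", "naive_bayes", "svm", "knn")


@dataclass(frozen=True)
class ModelSpec:
    """One family's tuning recipe."""

    family: str
    budget: int = 200  # hyperparameter-search evaluations
    cv_folds: int = 5
    seed: int = 0
    kernel: str | None = None  # svm only: fix the kernel instead of searching

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.budget < 1 or self.cv_folds < 2:
            raise ValueError("budget >= 1 and cv_folds >= 2 required")


def _sample_params(family: str, rng: np.random.Generator, kernel: str | None) -> dict:
    if family == "decision_tree":
        return {
            "max_depth": int(rng.integers(1, 31)),
            "min_samples_leaf": int(round(10 ** rng.uniform(0, 2))),
        }
    if family == "discriminant":
        if rng.random() < 0.5:
            return {"kind": "linear", "shrinkage": float(rng.uniform(0.0, 1.0))}
        return {"kind": "quadratic", "reg_param": float(rng.uniform(0.0, 0.5))}
    if family == "naive_bayes":
        return {"var_smoothing": float(10 ** rng.uniform(-12, -3))}
    if family == "svm":
        k = kernel or ("linear" if rng.random() < 0.5 else "rbf")
        params = {"kernel": k, "C": float(10 ** rng.uniform(-2, 3))}
        if k == "rbf":
            params["gamma"] = float(10 ** rng.uniform(-4, 1))
        return params
    if family == "knn":
        return {
            "n_neighbors": int(rng.integers(1, 51)),
            "metric": str(rng.choice(["euclidean", "cityblock", "cosine"])),
        }
    raise ValueError(family)


def _build_estimator(family: str, params: Mapping, seed: int) -> Pipeline:
    if family == "decision_tree":
        clf = DecisionTreeClassifier(
            max_depth=params["max_depth"],
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed,
        )
    elif family == "discriminant":
        if params["kind"] == "linear":
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=params["shrinkage"])
        else:
            clf = QuadraticDiscriminantAnalysis(reg_param=params["reg_param"])
    elif family == "naive_bayes":
        clf = GaussianNB(var_smoothing=params["var_smoothing"])
    elif family == "svm":
        clf = SVC(
            kernel=params["kernel"],
            C=params["C"],
            gamma=params.get("gamma", "scale"),
            random_state=seed,
            cache_size=256,
        )
    elif family == "knn":
        clf = KNeighborsClassifier(n_neighbors=params["n_neighbors"], metric=params["metric"])
    else:
        raise ValueError(family)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class TunedModel:
    spec: ModelSpec
    params: dict
    cv_accuracy: float
    estimator: Pipeline


def tune_and_train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
) -> TunedModel:
    """Random search with ``spec.budget`` candidate configurations, each
    scored by subject-grouped k-fold CV accuracy; the best is refit on all
    rows.  Deterministic under ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    rng = np.random.default_rng(spec.seed)
    if groups is None:
        groups = np.arange(len(y))
    n_groups = len(np.unique(groups))
    n_splits = min(spec.cv_folds, n_groups)
    if n_splits >= 2:
        folds = list(GroupKFold(n_splits=n_splits).split(X, y, groups))
    else:
        # single training subject: grouped CV is undefined, fall back to
        # plain k-fold within that subject
        warnings.warn("fewer than 2 subject groups; using ungrouped k-fold CV")
        kf = KFold(n_splits=min(spec.cv_folds, max(len(y) // 2, 2)))
        folds = list(kf.split(X, y))

    best: TunedModel | None = None
    seen: set[str] = set()
    for _ in range(spec.budget):
        params = _sample_params(spec.family, rng, spec.kernel)
        key = repr(sorted(params.items()))
        if key in seen:
            continue
        seen.add(key)
        accs = []
        for tr, va in folds:
            if len(np.unique(y[tr])) < 2:
                continue
            est = _build_estimator(spec.family, params, spec.seed)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[va]) == y[va])))
        score = float(np.mean(accs)) if accs else -1.0
        if best is None or score > best.cv_accuracy:
            est = _build_estimator(spec.family, params, spec.seed)
            best = TunedModel(spec, params, score, est)
    assert best is not None
    best.estimator.fit(X, y)
    return best


_UNDEF = float("nan")


def compute_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """The five confusion-matrix metrics.  Ratios with a zero denominator
    are returned as NaN (flagged undefined), never as 0."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "sens": tp / (tp + fn) if tp + fn else _UNDEF,
        "spec": tn / (tn + fp) if tn + fp else _UNDEF,
        "ppv": tp / (tp + fp) if tp + fp else _UNDEF,
        "npv": tn / (tn + fn) if tn + fn else _UNDEF,
        "acc": (tp + tn) / total,
    }


METRIC_NAMES = ("sens", "spec", "ppv", "npv", "acc")


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return tp, fn, tn, fp


@dataclass
class MetricsReport:
    """Mean +/- SD of each metric over evaluation repeats, plus the raw
    per-repeat confusion totals."""

    family: str
    per_repeat: pd.DataFrame  # columns: sens..acc, tp, fn, tn, fp

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat[list(METRIC_NAMES)].std(ddof=1).fillna(0.0)

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"family": self.family}  # type: ignore[dict-item]
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = float(self.mean[m])
            row[f"{m}_std"] = float(self.std[m])
        return row


def select_best_family(reports: Mapping[str, MetricsReport]) -> str:
    """Best tradeoff between diagnostic accuracy and balanced
    sensitivity/specificity: among families whose mean accuracy is within
    one SD of the best, pick the largest min(mean sens, mean spec)."""
    accs = {f: float(r.mean["acc"]) for f, r in reports.items()}
    best_f = max(accs, key=accs.get)
    tol = float(reports[best_f].std["acc"])
    eligible = [f for f, a in accs.items() if a >= accs[best_f] - tol]
    return max(
        eligible,
        key=lambda f: (
            min(float(reports[f].mean["sens"]), float(reports[f].mean["spec"])),
            accs[f],
        ),
    )
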