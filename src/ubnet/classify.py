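"""Repeated stratified k-fold evaluation of subgraph-feature classifiers.

The protocol mirrors common functional-connectivity classification studies:
an RBF-kernel SVM, a power-of-two (c, g) grid chosen by cross-validated
accuracy on the training portion, and stratified 10-fold cross-validation
repeated many times with metrics averaged over folds then repeats.

Two evaluation modes are provided.  ``pooled`` evaluates a fixed feature
matrix whose discriminative patterns were selected on the full cohort (the
protocol replicated from the study; selection sees test subjects, so scores
are optimistic).  ``nested`` re-runs mining and selection inside every
training fold, so the test fold never influences feature choice — the
methodologically clean default for synthetic experiments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .estimators import RbfSvmGridClassifier, SubgraphFeatureExtractor
from .features import FeatureMatrix
from .graph import UncertainNetwork

__all__ = ["CVConfig", "ClassificationReport", "grid_search_svm", "repeated_cv_evaluate"]

_SEED_MOD = 2**31 - 1


@dataclass
class CVConfig:
    """folds/repeats of the outer cross-validation, the (c, g) exponent
    grids, the evaluation mode and the root seed."""

    folds: int = 10
    repeats: int = 100
    c_exponents: tuple = tuple(range(-5, 6))
    g_exponents: tuple = tuple(range(-8, 3))
    inner_folds: int = 3
    seed: int = 0
    mode: str = "pooled"

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.c_exponents or not self.g_exponents:
            raise ValueError("parameter grids must be non-empty")
        if self.mode not in ("pooled", "nested"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ClassificationReport:
    """Mean metrics over repeats, per-repeat values, and the modal (c, g)."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    best_params: tuple
    per_repeat: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "best_params": {"c": self.best_params[0], "g": self.best_params[1]},
            "per_repeat": self.per_repeat,
        }


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _validate_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not set(np.unique(y)) == {-1, 1}:
        raise ValueError("labels must be -1/+1 with both classes present")
    return y


def grid_search_svm(X, y, config: CVConfig | None = None) -> tuple[float, float]:
    """Best (c, g) on the full training data by cross-validated accuracy;
    ties broken toward smaller c then smaller g."""
    config = config or CVConfig()
    clf = RbfSvmGridClassifier(
        c_exponents=config.c_exponents,
        g_exponents=config.g_exponents,
        inner_folds=config.inner_folds,
        random_state=config.seed % _SEED_MOD,
    )
    clf.fit(_as_array(X), _validate_labels(y))
    return clf.best_c_, clf.best_g_


def _fold_metrics(y_true, y_pred, scores) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    out = {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    if len(np.unique(y_true)) == 2:
        out["auc"] = roc_auc_score(y_true, scores)
    else:
        out["auc"] = np.nan
    return out


def repeated_cv_evaluate(
    X,
    y,
    config: CVConfig | None = None,
    *,
    networks: Sequence[UncertainNetwork] | None = None,
    extractor: SubgraphFeatureExtractor | None = None,
) -> ClassificationReport:
    """Repeated stratified k-fold evaluation.

    In ``pooled`` mode ``X`` is the (fixed) feature matrix.  In ``nested``
    mode ``networks`` and an unfitted ``extractor`` template must be given;
    a clone of the extractor is fitted on each training fold's networks
    only, and ``X`` is ignored.
    """
    config = config or CVConfig()
    y = _validate_labels(y)
    n_minority = min(np.sum(y == 1), np.sum(y == -1))
    if config.folds > n_minority:
        raise ValueError(
            f"folds={config.folds} exceeds the minority class size "
            f"({n_minority}); reduce folds or enlarge the cohort"
        )
    if config.mode == "nested":
        if networks is None or extractor is None:
            raise ValueError("nested mode requires networks= and extractor=")
        networks = list(networks)
        if len(networks) != len(y):
            raise ValueError("one label per network is required")
    else:
        X = _as_array(X)
        if X.shape[0] != len(y):
            raise ValueError("one label per row is required")

    per_repeat = []
    param_counts: Counter = Counter()
    for rep in range(config.repeats):
        rep_seed = (config.seed + 7919 * rep + 1) % _SEED_MOD
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rep_seed)
        fold_rows = []
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            y_tr, y_te = y[train_idx], y[test_idx]
            if config.mode == "nested":
                ext = clone(extractor)
                ext.fit([networks[i] for i in train_idx], y_tr)
                X_tr = ext.transform([networks[i] for i in train_idx])
                X_te = ext.transform([networks[i] for i in test_idx])
            else:
                X_tr, X_te = X[train_idx], X[test_idx]
            clf = RbfSvmGridClassifier(
                c_exponents=config.c_exponents,
                g_exponents=config.g_exponents,
                inner_folds=config.inner_folds,
                random_state=rep_seed,
            )
            clf.fit(X_tr, y_tr)
            param_counts[(clf.best_c_, clf.best_g_)] += 1
            y_pred = clf.predict(X_te)
            scores = clf.decision_function(X_te)
            fold_rows.append(_fold_metrics(y_te, y_pred, scores))
        per_repeat.append(
            {
                m: float(np.nanmean([row[m] for row in fold_rows]))
                for m in ("accuracy", "sensitivity", "specificity", "auc")
            }
        )
    best_params = min(
        (p for p, c in param_counts.items() if c == max(param_counts.values())),
    )
    return ClassificationReport(
        accuracy=float(np.mean([r["accuracy"] for r in per_repeat])),
        sensitivity=float(np.mean([r["sensitivity"] for r in per_repeat])),
        specificity=float(np.mean([r["specificity"] for r in per_repeat])),
        auc=float(np.mean([r["auc"] for r in per_repeat])),
        best_params=best_params,
        per_repeat=per_repeat,
    )
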