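"""Composite-score benchmarking of feature sets.

Each method's selected feature set is scored across ten classifier families
with stratified tenfold cross-validation on five indexes (Pre, Acc, Auc,
F1, Recall).  The composite score CS of a feature set is the grand mean of
the 10 x 5 matrix, ``CS = (1/(K*M)) * sum_{k,m} index(k, model(m, F))``
with K = 5 indexes and M = 10 models; the method attaining the highest CS
is the best selection method.

The "paper" model registry mirrors the reference settings (RBF SVM,
decision tree, AdaBoost, MLP(400,100), 200-tree random forest, k-NN,
cross-validated logistic regression, LDA, gradient boosting, Gaussian
naive Bayes); the "fast" registry keeps the same ten families with lighter
settings for desk-scale runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_NAMES", "INDEX_NAMES", "model_registry", "compute_indexes",
    "crossval_metrics", "composite_score", "benchmark_feature_sets",
    "select_best_method", "CompositeScoreReport",
]

log = logging.getLogger(__name__)

MODEL_NAMES = ("SVM", "DT", "Ada", "NN", "RF", "KNN", "LR", "DA", "GBDT", "NB")
INDEX_NAMES = ("Pre", "Acc", "Auc", "F1", "Recall")


def model_registry(profile: str = "paper", seed: int = 0) -> dict:
    """The ten classifier families as fresh estimator instances."""
    if profile == "paper":
        return {
            "SVM": SVC(kernel="rbf", probability=True, random_state=seed),
            "DT": DecisionTreeClassifier(random_state=seed),
            "Ada": AdaBoostClassifier(random_state=seed),
            "NN": MLPClassifier(hidden_layer_sizes=(400, 100), alpha=0.01,
                                max_iter=10000, random_state=seed),
            "RF": RandomForestClassifier(n_estimators=200, random_state=seed),
            "KNN": KNeighborsClassifier(),
            "LR": OneVsRestClassifier(
                LogisticRegressionCV(max_iter=100000, solver="liblinear",
                                     random_state=seed)),
            "DA": LinearDiscriminantAnalysis(),
            "GBDT": GradientBoostingClassifier(random_state=seed),
            "NB": GaussianNB(),
        }
    if profile == "fast":
        return {
            "SVM": SVC(kernel="rbf", probability=True, random_state=seed),
            "DT": DecisionTreeClassifier(random_state=seed),
            "Ada": AdaBoostClassifier(n_estimators=20, random_state=seed),
            "NN": MLPClassifier(hidden_layer_sizes=(16,), alpha=0.01,
                                max_iter=400, random_state=seed),
            "RF": RandomForestClassifier(n_estimators=50, random_state=seed),
            "KNN": KNeighborsClassifier(),
            "LR": OneVsRestClassifier(
                LogisticRegression(max_iter=5000, solver="liblinear",
                                   random_state=seed)),
            "DA": LinearDiscriminantAnalysis(),
            "GBDT": GradientBoostingClassifier(n_estimators=30,
                                               random_state=seed),
            "NB": GaussianNB(),
        }
    raise ValueError(f"unknown model profile {profile!r}")


def compute_indexes(model, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """The five indexes on held-out data.  Multi-class: macro averaging,
    one-vs-rest Auc."""
    y_pred = model.predict(X_test)
    proba = model.predict_proba(X_test)
    classes = model.classes_
    if len(classes) == 2:
        auc = roc_auc_score(y_test, proba[:, 1])
        avg = "binary" if set(classes) == {0, 1} else "macro"
    else:
        auc = roc_auc_score(y_test, proba, multi_class="ovr",
                            average="macro", labels=classes)
        avg = "macro"
    return {
        "Pre": float(precision_score(y_test, y_pred, average=avg,
                                     zero_division=0)),
        "Acc": float(accuracy_score(y_test, y_pred)),
        "Auc": float(auc),
        "F1": float(f1_score(y_test, y_pred, average=avg, zero_division=0)),
        "Recall": float(recall_score(y_test, y_pred, average=avg,
                                     zero_division=0)),
    }


def crossval_metrics(features: pd.DataFrame, labels, models: dict | None = None,
                     folds: int = 10, seed: int = 0,
                     repeats: int = 1) -> pd.DataFrame:
    """Mean cross-validated value of each index for each model: the
    models x indexes MetricsMatrix.

    Stratified folds with a fixed shuffle seed; a fold whose training part
    lacks a class raises (the caller should reduce ``folds``).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if models is None:
        models = model_registry("paper", seed)
    counts = np.bincount(pd.factorize(y)[0])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify "
            f"into {folds} folds")
    rows = {name: {k: [] for k in INDEX_NAMES} for name in models}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + rep)
        for tr, te in skf.split(X, y):
            for name, proto in models.items():
                m = clone(proto)
                m.fit(X[tr], y[tr])
                for k, v in compute_indexes(m, X[te], y[te]).items():
                    rows[name][k].append(v)
    return pd.DataFrame({name: {k: float(np.mean(v)) for k, v in d.items()}
                         for name, d in rows.items()}).T[list(INDEX_NAMES)]


def composite_score(matrix: pd.DataFrame) -> float:
    """Grand mean over all model x index cells."""
    if matrix.isna().any().any():
        raise ValueError("metrics matrix has missing cells")
    return float(matrix.to_numpy(dtype=float).mean())


@dataclass
class CompositeScoreReport:
    matrices: dict          # method -> MetricsMatrix DataFrame
    cs: dict                # method -> composite score
    best_method: str


def select_best_method(cs: dict) -> str:
    """Argmax of the composite score; exact ties go to the alphabetically
    first method (logged)."""
    if not cs:
        raise ValueError("no composite scores")
    best = max(sorted(cs), key=lambda m: cs[m])
    ties = [m for m in cs if cs[m] == cs[best] and m != best]
    if ties:
        log.info("CS tie between %s and %s; keeping %s",
                 best, ties, best)
    return best


def benchmark_feature_sets(feature_sets: dict, table: pd.DataFrame, labels,
                           models: dict | None = None, folds: int = 10,
                           seed: int = 0, repeats: int = 1
                           ) -> CompositeScoreReport:
    """Cross-validate every method's feature set and rank by CS.

    ``feature_sets`` maps method name -> FeatureSet; methods with an empty
    selection are scored 0 (they cannot classify anything).
    """
    matrices, cs = {}, {}
    for method, fs in feature_sets.items():
        if not fs.features:
            log.warning("method %s has an empty feature set; CS = 0", method)
            matrices[method] = pd.DataFrame(
                0.0, index=list((models or model_registry()).keys()),
                columns=list(INDEX_NAMES))
            cs[method] = 0.0
            continue
        mat = crossval_metrics(table[fs.features], labels, models=models,
                               folds=folds, seed=seed, repeats=repeats)
        matrices[method] = mat
        cs[method] = composite_score(mat)
    return CompositeScoreReport(matrices=matrices, cs=cs,
                                best_method=select_best_method(cs))
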