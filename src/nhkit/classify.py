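"""Leave-one-out SVM discrimination on cluster-NH features.

Each held-out subject is predicted by an SVM trained on the remaining n-1,
with feature standardization fit inside the training fold only. Every
nonempty feature subset (up to a size cap) is scored and the best combination
is chosen by accuracy, ties broken by fewer features then lexicographic ids.
The melancholic group is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ClassificationResult", "metrics", "loocv_svm", "enumerate_combinations"]


@dataclass(frozen=True)
class ClassificationResult:
    features: tuple[str, ...]
    predictions: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float


def metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Accuracy / sensitivity / specificity as percentages at 2-decimal
    reporting precision. Sensitivity is computed on the positive class."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    n = tp + fn + tn + fp
    if n == 0 or (tp + fn) == 0 or (tn + fp) == 0:
        raise ZeroDivisionError("empty class")
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return round(acc, 2), round(sens, 2), round(spec, 2)


def _make_svm(kernel: str, c: float, gamma) -> SVC:
    return SVC(kernel=kernel, C=c, gamma=gamma)


def loocv_svm(
    features: np.ndarray,
    labels: np.ndarray,
    positive_label: str = "melancholic",
    kernel: str = "rbf",
    c: float = 1.0,
    gamma="auto",  # 1 / n_features
    feature_names: tuple[str, ...] = (),
    standardize: bool = True,
) -> ClassificationResult:
    """Leave-one-out cross-validated SVM over a two-class feature matrix."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.ndim != 2:
        raise ValueError("features must be 2D (subjects x features)")
    labels = np.asarray(labels)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if np.unique(labels[train]).size < 2:
            raise ValueError("a training fold lost a class")
        xtr, xte = x[train], x[i : i + 1]
        if standardize:
            scaler = StandardScaler().fit(xtr)
            xtr, xte = scaler.transform(xtr), scaler.transform(xte)
        clf = _make_svm(kernel, c, gamma)
        clf.fit(xtr, labels[train])
        preds[i] = clf.predict(xte)[0]
    pos = labels == positive_label
    tp = int(((preds == labels) & pos).sum())
    fn = int(((preds != labels) & pos).sum())
    tn = int(((preds == labels) & ~pos).sum())
    fp = int(((preds != labels) & ~pos).sum())
    acc, sens, spec = metrics(tp, fn, tn, fp)
    return ClassificationResult(tuple(feature_names), preds, tp, fn, tn, fp, acc, sens, spec)


def enumerate_combinations(
    features: pd.DataFrame,
    labels: np.ndarray,
    max_subset: int | None = None,
    positive_label: str = "melancholic",
    **svm_kwargs,
) -> tuple[list[ClassificationResult], ClassificationResult]:
    """Score every nonempty feature subset up to ``max_subset`` columns.

    Best = highest accuracy; ties go to the smaller subset, then to the
    lexicographically first tuple of feature names.
    """
    names = list(features.columns)
    if not names:
        raise ValueError("need at least one feature")
    k_max = len(names) if max_subset is None else min(max_subset, len(names))
    results: list[ClassificationResult] = []
    for k in range(1, k_max + 1):
        for combo in combinations(names, k):
            res = loocv_svm(
                features[list(combo)].to_numpy(),
                labels,
                positive_label=positive_label,
                feature_names=combo,
                **svm_kwargs,
            )
            results.append(res)
    best = min(results, key=lambda r: (-r.accuracy_pct, len(r.features), r.features))
    return results, best
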