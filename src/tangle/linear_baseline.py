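"""n-BOW featurization and the l1-penalized logistic regression baseline.

Each subject's item sequence is reduced to occurrence counts of consecutive
item n-grams (time spans are ignored). The classifier minimizes

    (1/N) sum_i log(1 + exp(-y_i x_i^T w)) + gamma * |w|_1

with y in {-1, +1}; gamma is chosen from a log-spaced grid by validation
ROC AUC. The solver is scikit-learn's liblinear with C = 1 / (N * gamma),
which optimizes the same objective up to the constant rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .claims_io import ClaimSequence

__all__ = ["BowFeatures", "default_gamma_grid", "nbow_features", "fit_l1_lr"]


@dataclass
class BowFeatures:
    counts: sp.csr_matrix  # (N, d) non-negative integer counts
    feature_names: list[tuple[str, ...]]
    n: int

    @property
    def index(self) -> dict[tuple[str, ...], int]:
        return {g: i for i, g in enumerate(self.feature_names)}


def default_gamma_grid() -> np.ndarray:
    """10 log-spaced penalty values from 1e-5 to 1."""
    return np.logspace(-5, 0, 10)


def nbow_features(sequences: Sequence[ClaimSequence], n: int = 1,
                  feature_space: Optional[list[tuple[str, ...]]] = None) -> BowFeatures:
    """Count consecutive item n-grams per subject.

    When ``feature_space`` is given (test-time), n-grams outside it are
    dropped; otherwise the feature space is the set of n-grams observed in
    the corpus, in first-appearance order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if feature_space is not None:
        index = {g: i for i, g in enumerate(feature_space)}
        names = list(feature_space)
        grow = False
    else:
        index, names, grow = {}, [], True
    rows, cols, vals = [], [], []
    for i, seq in enumerate(sequences):
        items = seq.items()
        counts: dict[int, int] = {}
        for p in range(len(items) - n + 1):
            gram = tuple(items[p:p + n])
            j = index.get(gram)
            if j is None:
                if not grow:
                    continue
                j = len(names)
                index[gram] = j
                names.append(gram)
            counts[j] = counts.get(j, 0) + 1
        rows.extend([i] * len(counts))
        cols.extend(counts.keys())
        vals.extend(counts.values())
    X = sp.csr_matrix((vals, (rows, cols)),
                      shape=(len(sequences), len(names)), dtype=np.float64)
    return BowFeatures(X, names, n)


def fit_l1_lr(X_train, y_train, X_val, y_val,
              gamma_grid: Optional[np.ndarray] = None, seed: int = 0):
    """Fit the l1-LR over the gamma grid; pick gamma by validation ROC AUC.

    Returns a dict with the winning gamma, its weight vector, the refit
    estimator and the per-gamma path (validation AUC, nonzero counts).
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    gamma_grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid)
    N = X_train.shape[0]
    path = []
    best = None
    for gamma in gamma_grid:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (N * gamma), solver="liblinear",
            fit_intercept=False, max_iter=2000, tol=1e-8, random_state=seed,
        )
        clf.fit(X_train, y_train)
        w = clf.coef_.ravel()
        auc = roc_auc_score(y_val, clf.decision_function(X_val))
        path.append({"gamma": float(gamma), "val_auc": float(auc),
                     "nonzero": int(np.count_nonzero(w))})
        if best is None or auc > best["val_auc"]:
            best = {"gamma": float(gamma), "val_auc": float(auc),
                    "weights": w, "estimator": clf}
    best["path"] = path
    return best
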