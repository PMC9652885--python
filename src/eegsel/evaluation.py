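"""Leave-pair-out cross-validated scoring of a feature table.

Each fold holds out one subject per class. Per fold the training rows are
z-scored, features are ranked by Fisher score on the training data, and an
SVM is trained on the top-N features for N = 1..max_features. Sensitivity is
the MCI detection rate, specificity the HC detection rate, and accuracy is
their mean (exact, since every fold tests one subject per class).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FeatureTable, build_feature_table, feature_schema  # noqa: F401

POSITIVE_CLASS = "MCI"
NEGATIVE_CLASS = "HC"


def fisher_score(values: np.ndarray, labels: Sequence[str]) -> float:
    """Two-class Fisher score (mu1 - mu2)^2 / (var1 + var2), unbiased class
    variances. Zero iff the class means are equal; a zero denominator with
    unequal means gives +inf (the feature separates the training classes
    perfectly and must rank first)."""
    return float(fisher_scores(np.asarray(values, dtype=float).reshape(-1, 1),
                               labels)[0])


def fisher_scores(X: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Columnwise Fisher scores for a subjects x features matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    pos = y == POSITIVE_CLASS
    neg = y == NEGATIVE_CLASS
    if pos.sum() < 1 or neg.sum() < 1:
        raise ValueError("both classes must be represented")

    def class_var(rows: np.ndarray) -> np.ndarray:
        # single-subject classes contribute no variance estimate
        return rows.var(axis=0, ddof=1) if rows.shape[0] >= 2 else np.zeros(X.shape[1])

    mu_diff = X[pos].mean(axis=0) - X[neg].mean(axis=0)
    denom = class_var(X[pos]) + class_var(X[neg])
    scores = np.zeros(X.shape[1])
    ok = denom > 0
    scores[ok] = mu_diff[ok] ** 2 / denom[ok]
    degenerate = ~ok & (mu_diff != 0)
    if degenerate.any():
        warnings.warn("zero within-class variance with unequal means; "
                      "score set to inf", RuntimeWarning)
        scores[degenerate] = np.inf
    return scores


def lpo_folds(n_mci: int, n_hc: int) -> List[Tuple[Tuple[int, int], np.ndarray]]:
    """Leave-pair-out folds over subjects indexed 0..n_mci-1 (MCI) and
    n_mci..n_mci+n_hc-1 (HC).

    Returns (test_pair, train_indices) per fold, ordered by MCI subject then
    HC subject, n_mci * n_hc folds total.
    """
    if n_mci < 2 or n_hc < 2:
        raise ValueError(
            "need at least 2 subjects per group (training set would be empty "
            "or single-class)")
    n = n_mci + n_hc
    folds = []
    for i in range(n_mci):
        for j in range(n_hc):
            test = (i, n_mci + j)
            train = np.array([t for t in range(n) if t not in test])
            folds.append((test, train))
    return folds


@dataclass
class CVResult:
    """Cross-validation scores. Rates are percentages in [0, 100]."""

    per_n_accuracy: np.ndarray
    per_n_sensitivity: np.ndarray
    per_n_specificity: np.ndarray
    best_n: int
    accuracy: float
    sensitivity: float
    specificity: float
    block_sd: float
    n_folds: int
    kernel: str = "linear"
    max_features: int = 15

    def to_dict(self) -> dict:
        return {
            "best_N": self.best_n,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "block_sd": self.block_sd,
            "n_folds": self.n_folds,
            "svm_kernel": self.kernel,
            "per_N": [
                {"N": i + 1, "accuracy": float(a), "sensitivity": float(s),
                 "specificity": float(p)}
                for i, (a, s, p) in enumerate(zip(
                    self.per_n_accuracy, self.per_n_sensitivity,
                    self.per_n_specificity))
            ],
        }


def _zscore_train_test(train: np.ndarray, test: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd_safe, (test - mean) / sd_safe


def evaluate_configuration(
    subtable: FeatureTable,
    max_features: int = 15,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> CVResult:
    """Leave-pair-out CV with per-fold z-scoring, Fisher-score feature
    ranking and an N-feature sweep of an SVM classifier.

    ``block_sd`` is the standard deviation of mean accuracy across the
    n_mci blocks of folds sharing the same held-out MCI subject, at best N.
    """
    y = subtable.labels.to_numpy()
    order = np.argsort(np.where(y == POSITIVE_CLASS, 0, 1), kind="stable")
    X = subtable.values.to_numpy(dtype=float)[order]
    y = y[order]
    n_mci = int((y == POSITIVE_CLASS).sum())
    n_hc = int((y == NEGATIVE_CLASS).sum())
    n_feat = X.shape[1]
    if n_feat == 0:
        raise ValueError("empty feature table")
    if max_features > n_feat:
        warnings.warn(f"max_features={max_features} capped to {n_feat} "
                      "available features", RuntimeWarning)
        max_features = n_feat

    folds = lpo_folds(n_mci, n_hc)
    n_folds = len(folds)
    correct_mci = np.zeros((max_features, n_folds), dtype=float)
    correct_hc = np.zeros((max_features, n_folds), dtype=float)

    yy = (y == POSITIVE_CLASS).astype(int)
    for f, ((ti, tj), train_idx) in enumerate(folds):
        X_train, X_test = X[train_idx], X[[ti, tj]]
        y_train = yy[train_idx]
        Z_train, Z_test = _zscore_train_test(X_train, X_test)
        scores = fisher_scores(Z_train, y[train_idx])
        # stable argsort descending -> ties broken by column order
        rank = np.argsort(-scores, kind="stable")[:max_features]
        for n_sel in range(1, max_features + 1):
            cols = rank[:n_sel]
            clf = SVC(kernel=kernel, C=C, gamma=gamma)
            clf.fit(Z_train[:, cols], y_train)
            pred = clf.predict(Z_test[:, cols])
            correct_mci[n_sel - 1, f] = float(pred[0] == 1)
            correct_hc[n_sel - 1, f] = float(pred[1] == 0)

    sens = correct_mci.mean(axis=1) * 100.0
    spec = correct_hc.mean(axis=1) * 100.0
    acc = (sens + spec) / 2.0
    best = int(np.argmax(acc))  # ties -> smallest N

    fold_acc = (correct_mci[best] + correct_hc[best]) / 2.0 * 100.0
    blocks = fold_acc.reshape(n_mci, n_hc).mean(axis=1)
    block_sd = float(blocks.std(ddof=1)) if n_mci > 1 else 0.0

    return CVResult(
        per_n_accuracy=acc, per_n_sensitivity=sens, per_n_specificity=spec,
        best_n=best + 1, accuracy=float(acc[best]),
        sensitivity=float(sens[best]), specificity=float(spec[best]),
        block_sd=block_sd, n_folds=n_folds, kernel=kernel,
        max_features=max_features)
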