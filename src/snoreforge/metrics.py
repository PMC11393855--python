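"""Evaluation metric and cross-validation helpers.

Unweighted Average Recall (UAR) — the mean of per-class recalls — is the
standard score in computational paralinguistics because it is insensitive
to class imbalance: a majority-class constant predictor on C balanced
classes scores exactly 1/C.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["uar", "stratified_folds"]


def uar(y_true, y_pred) -> float:
    """Mean of per-class recalls, in [0, 1].

    Classes that appear only in predictions are ignored; a class present
    in neither recall denominator is an error.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be non-empty and aligned")
    recalls = []
    for c in np.unique(y_true):
        in_class = y_true == c
        if not in_class.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"class {c!r} has no true samples")
        recalls.append(np.mean(y_pred[in_class] == c))
    return float(np.mean(recalls))


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample, class proportions preserved per fold."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer samples than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment
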