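"""Multiclass Adaboost over weighted-ELM weak learners, plus the
regression-style combiner used to fuse swarm-tuned WELM predictors.

The boost follows the multiclass SAMME scheme with a class-imbalance-aware
initial distribution (w_i proportional to 1/class count, normalized so every
class carries equal mass). Learner weights are
alpha_t = ln((1-eps_t)/eps_t) + ln(C-1); a round is useful only while
eps_t < (C-1)/C. The sample update multiplies correctly classified
samples by exp(-alpha) and renormalizes, which after normalization is
exactly SAMME's usual exp(+alpha on mistakes) update.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .elm import WELMClassifier

__all__ = [
    "init_boost_weights", "weak_error", "learner_alpha", "update_boost_weights",
    "AdaBoostWELMClassifier", "adaboost_predict", "regressor_combine",
]

_EPS_FLOOR = 1e-10


def init_boost_weights(y: np.ndarray) -> np.ndarray:
    """Initial distribution: w_i proportional to 1/class count, summing to 1."""
    y = np.asarray(y)
    classes, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    w = 1.0 / counts[inverse]
    return w / w.sum()


def weak_error(pred: np.ndarray, y: np.ndarray, dist: np.ndarray) -> float:
    """Distribution-weighted misclassification rate eps = sum_i d_i [pred_i != y_i]."""
    pred, y, dist = map(np.asarray, (pred, y, dist))
    if not (pred.size == y.size == dist.size):
        raise ValueError("pred, y and dist must align")
    return float(dist[pred != y].sum())


def learner_alpha(epsilon: float, n_classes: int) -> float:
    """alpha = ln((1-eps)/eps) + ln(C-1); positive iff eps < (C-1)/C."""
    eps = max(float(epsilon), _EPS_FLOOR)  # eps = 0 capped
    if eps >= 1.0:
        raise ValueError("error rate must be below 1")
    return float(np.log((1.0 - eps) / eps) + np.log(n_classes - 1))


def update_boost_weights(dist: np.ndarray, pred: np.ndarray, y: np.ndarray,
                         alpha: float) -> np.ndarray:
    """w_i <- w_i * exp(-alpha * 1[pred_i = y_i]), renormalized to sum 1."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    correct = (np.asarray(pred) == np.asarray(y)).astype(np.float64)
    w = np.asarray(dist, dtype=np.float64) * np.exp(-alpha * correct)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate boosting distribution")
    return w / total


class AdaBoostWELMClassifier(BaseEstimator, ClassifierMixin):
    """Adaboost ensemble of weighted-ELM (or kernel-WELM) weak learners.

    Each round trains a clone of ``base`` with the current boosting
    distribution folded into its sample weights (U = diag(dist * N)) and a
    round-specific hidden-layer seed. Training stops early when a learner
    is perfect (eps = 0) or no better than chance (eps >= (C-1)/C); if no
    round is usable, a single unboosted learner is kept with a warning.

    Attributes
    ----------
    learners_ : list of fitted weak learners
    alphas_ : ndarray of vote weights, all positive
    history_ : per-round weighted errors eps_t
    """

    def __init__(self, base=None, n_rounds: int = 10, random_state: int = 0):
        self.base = base
        self.n_rounds = n_rounds
        self.random_state = random_state

    def _make_learner(self, round_idx: int):
        base = self.base if self.base is not None else WELMClassifier(n_hidden=50, ridge=0.01)
        learner = clone(base)
        if "random_state" in learner.get_params():
            learner.set_params(random_state=self.random_state + 1000 * round_idx)
        return learner

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        C = self.classes_.size
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        dist = init_boost_weights(y)
        n = y.size
        self.learners_, alphas, self.history_ = [], [], []
        for t in range(self.n_rounds):
            learner = self._make_learner(t)
            learner.fit(X, y, sample_weight=dist * n)
            pred = learner.predict(X)
            eps = weak_error(pred, y, dist)
            self.history_.append(eps)
            if eps >= (C - 1) / C:
                break  # no better than chance: reject the round
            alpha = learner_alpha(eps, C)
            self.learners_.append(learner)
            alphas.append(alpha)
            if eps <= _EPS_FLOOR:
                break  # perfect learner; further rounds are redundant
            dist = update_boost_weights(dist, pred, y, alpha)
        if not self.learners_:
            warnings.warn("no boosting round beat chance; falling back to a single learner")
            learner = self._make_learner(0)
            learner.fit(X, y)
            self.learners_ = [learner]
            alphas = [1.0]
        self.alphas_ = np.asarray(alphas)
        self.rounds_run_ = len(self.learners_)
        return self

    def predict(self, X):
        return adaboost_predict(self.learners_, self.alphas_, self.classes_, X)

    def decision_function(self, X):
        votes = np.zeros((np.asarray(X).shape[0], self.classes_.size))
        for learner, alpha in zip(self.learners_, self.alphas_):
            pred = learner.predict(X)
            idx = np.searchsorted(self.classes_, pred)
            votes[np.arange(votes.shape[0]), idx] += alpha
        return votes


def adaboost_predict(learners, alphas, classes, X) -> np.ndarray:
    """Weighted vote: argmax_c sum_t alpha_t 1[label_t(p) = c]; ties -> lowest index."""
    classes = np.asarray(classes)
    votes = np.zeros((np.asarray(X).shape[0], classes.size))
    for learner, alpha in zip(learners, alphas):
        idx = np.searchsorted(classes, learner.predict(X))
        votes[np.arange(votes.shape[0]), idx] += alpha
    return classes[np.argmax(votes, axis=1)]


def regressor_combine(predictors, X_train, y_train):
    """Adaboost-regressor-style fusion of fitted classifiers' decision scores.

    Per predictor h_k (on the current distribution T_k, initially uniform):
    per-sample error eps_k^i = |h_k(P_i) - q_i| / R with R the worst error,
    total error eps_k = sum_i T_k^i eps_k^i, beta = eps_k/(1-eps_k),
    c_k = 0.5*log(1/beta); the distribution is updated T_i <- T_i*beta^(-eps_i)
    and renormalized. Targets are the +/-1 one-vs-all encoding, errors
    averaged over classes. Predictors with eps_k >= 0.5 are dropped.

    Returns (weights summing to 1, kept predictors, combine(X) -> labels).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    T_onehot = -np.ones((y_train.size, classes.size))
    T_onehot[np.arange(y_train.size), np.searchsorted(classes, y_train)] = 1.0

    dist = np.full(y_train.size, 1.0 / y_train.size)
    kept, cs = [], []
    for h in predictors:
        scores = np.asarray(h.decision_function(X_train), dtype=np.float64)
        per_sample = np.abs(scores - T_onehot).mean(axis=1)
        R = per_sample.max()
        eps_i = per_sample / R if R > 0 else np.zeros_like(per_sample)
        eps_k = float(np.dot(dist, eps_i))
        if eps_k >= 0.5:
            continue  # beta >= 1 would give a non-positive coefficient
        beta = max(eps_k, _EPS_FLOOR) / (1.0 - eps_k)
        cs.append(0.5 * np.log(1.0 / beta))
        kept.append(h)
        dist = dist * beta ** (-eps_i)
        dist = dist / dist.sum()
    if not kept:
        raise ValueError("every predictor was dropped (error >= 0.5)")
    w = np.asarray(cs) / np.sum(cs)

    def combine(X):
        fused = sum(wi * np.asarray(h.decision_function(X)) for wi, h in zip(w, kept))
        return classes[np.argmax(fused, axis=1)]

    return w, kept, combine
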