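"""Extreme learning machines: ELM, Weighted ELM, (composited-)kernel WELM.

An ELM is a single-hidden-layer network whose hidden parameters (input
weights v_k, biases b_k) are drawn at random and never trained; only the
output weights beta are fit, in closed form, by ridge-regularized least
squares against +/-1 one-vs-all targets:

    beta = H^T (lam I + H H^T)^-1 T    (N <= D)
         = (lam I + H^T H)^-1 H^T T    (N >= D)

The two branches are algebraically identical; both are implemented and
tested against each other. The weighted variant multiplies sample i's
row by sqrt(u_i) (u_i = 1/class count by default), which is the symmetric
equivalent of inserting the diagonal weight matrix U into the solve and
raises the influence of minority-class samples. The kernel variant
replaces H H^T by a Gram matrix; the composited kernel blends an RBF on
one feature view with a polynomial kernel on another,
k = mu*K_rbf + (1-mu)*K_poly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "class_weights", "kernel_matrix", "composited_kernel",
    "ELMClassifier", "WELMClassifier", "KernelWELMClassifier",
]

_ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "identity": lambda z: z,
}


def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights w_i = 1 / (count of samples in i's class).

    Every class then carries equal total weight (each class sums to 1).
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    _, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def _one_hot_pm1(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    T = -np.ones((y_idx.size, n_classes))
    T[np.arange(y_idx.size), y_idx] = 1.0
    return T


def _ridge_solve(H: np.ndarray, T: np.ndarray, lam: float, *, force_branch: str | None = None
                 ) -> np.ndarray:
    """beta from either branch of the regularized least-squares solution."""
    n, d = H.shape
    branch = force_branch or ("dual" if n <= d else "primal")
    if branch == "dual":
        G = H @ H.T
        G.flat[:: n + 1] += lam
        return H.T @ np.linalg.solve(G, T)
    G = H.T @ H
    G.flat[:: d + 1] += lam
    return np.linalg.solve(G, H.T @ T)


def kernel_matrix(Xa: np.ndarray, Xb: np.ndarray, kind: str = "rbf", *,
                  gamma: float = 1.0, degree: int = 2) -> np.ndarray:
    """RBF exp(-gamma ||x-y||^2) or polynomial (<x,y> + 1)^degree Gram matrix."""
    Xa = np.atleast_2d(np.asarray(Xa, dtype=np.float64))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=np.float64))
    if kind == "rbf":
        aa = (Xa**2).sum(axis=1)[:, None]
        bb = (Xb**2).sum(axis=1)[None, :]
        sq = np.maximum(aa + bb - 2.0 * Xa @ Xb.T, 0.0)
        return np.exp(-gamma * sq)
    if kind in ("poly", "polynomial"):
        return (Xa @ Xb.T + 1.0) ** degree
    raise ValueError(f"unknown kernel kind {kind!r}")


def composited_kernel(Xa: np.ndarray, Xb: np.ndarray, view1: np.ndarray,
                      view2: np.ndarray, *, mu: float = 0.5, gamma: float = 1.0,
                      degree: int = 2) -> np.ndarray:
    """mu * RBF on the view1 columns + (1 - mu) * polynomial on the view2 columns."""
    view1 = np.asarray(view1)
    view2 = np.asarray(view2)
    if view1.size == 0 or view2.size == 0:
        raise ValueError("composited kernel requires two non-empty feature views")
    Ks = kernel_matrix(Xa[:, view1], Xb[:, view1], "rbf", gamma=gamma)
    Kw = kernel_matrix(Xa[:, view2], Xb[:, view2], "poly", degree=degree)
    return mu * Ks + (1.0 - mu) * Kw


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine with random hidden layer and ridge output solve.

    Parameters
    ----------
    n_hidden : int
        Hidden nodes D; input weights uniform [-1, 1], biases uniform [0, 1].
    ridge : float
        Regularization lam added to the normal equations.
    activation : {'sigmoid', 'tanh', 'identity'}
    random_state : int
        Seeds the hidden-layer draw; fixed seed gives identical models.
    hidden : (input_weights, biases) or None
        Externally chosen hidden parameters (e.g. swarm-tuned); overrides
        the random draw and survives cloning.
    """

    def __init__(self, n_hidden: int = 100, ridge: float = 0.1,
                 activation: str = "sigmoid", random_state: int = 0,
                 hidden=None):
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.activation = activation
        self.random_state = random_state
        self.hidden = hidden

    def _init_hidden(self, d: int) -> None:
        rng = np.random.default_rng(self.random_state)
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(self.n_hidden, d))
        self.biases_ = rng.uniform(0.0, 1.0, size=self.n_hidden)

    def set_hidden(self, input_weights: np.ndarray, biases: np.ndarray) -> "ELMClassifier":
        """Install externally chosen hidden parameters (used by the swarm tuners)."""
        self.hidden = (np.asarray(input_weights, dtype=np.float64),
                       np.asarray(biases, dtype=np.float64))
        return self

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """H[i, k] = s(<v_k, x_i> + b_k)."""
        check_is_fitted(self, "input_weights_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.input_weights_.shape[1]:
            raise ValueError("feature count does not match the fitted model")
        act = _ACTIVATIONS[self.activation]
        return act(X @ self.input_weights_.T + self.biases_)

    def _sample_weights(self, y: np.ndarray) -> np.ndarray | None:
        return None  # plain ELM treats every sample equally

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        if self.ridge <= 0:
            raise ValueError("ridge must be positive")
        if self.hidden is not None:
            W, b = self.hidden
            self.input_weights_ = np.asarray(W, dtype=np.float64)
            self.biases_ = np.asarray(b, dtype=np.float64)
        else:
            self._init_hidden(X.shape[1])
        H = self.hidden_activations(X)
        T = _one_hot_pm1(y_idx, self.classes_.size)
        w = sample_weight if sample_weight is not None else self._sample_weights(y)
        if w is not None:
            w = np.asarray(w, dtype=np.float64)
            if np.any(w <= 0):
                raise ValueError("sample weights must be positive")
            s = np.sqrt(w)[:, None]
            H, T = H * s, T * s
        self.output_weights_ = _ridge_solve(H, T, self.ridge)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "output_weights_")
        return self.hidden_activations(np.asarray(X, dtype=np.float64)) @ self.output_weights_

    def predict(self, X):
        f = self.decision_function(X)
        # ties broken toward the lowest class index (argmax keeps the first max)
        return self.classes_[np.argmax(f, axis=1)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "output_weights_")
        return {
            "kind": type(self).__name__,
            "input_weights": self.input_weights_.tolist(),
            "biases": self.biases_.tolist(),
            "output_weights": self.output_weights_.tolist(),
            "classes": self.classes_.tolist(),
            "params": self.get_params(),
        }


class WELMClassifier(ELMClassifier):
    """Weighted ELM: minority classes up-weighted with w_i = 1/class count.

    With uniform weights it reduces exactly to :class:`ELMClassifier`.
    Explicit ``sample_weight`` in :meth:`fit` overrides the class scheme
    (the Adaboost wrapper uses this to fold in its boosting distribution).
    """

    def _sample_weights(self, y: np.ndarray) -> np.ndarray:
        return class_weights(y)


class KernelWELMClassifier(BaseEstimator, ClassifierMixin):
    """Weighted kernel ELM; supports RBF, polynomial and composited kernels.

    The solve is the symmetric weighted form
    beta = S (lam I + S Omega S)^-1 S T with S = U^(1/2), equivalent to
    (lam I + U Omega)^-1 U T; prediction of a new point p uses the kernel
    row [k(p, p_1) ... k(p, p_N)] against the stored training anchors.

    ``view_split`` for the composited kernel is (view1_idx, view2_idx) or a
    feature-name prefix pair resolved against ``feature_names``.
    """

    def __init__(self, kernel: str = "rbf", gamma: float = 1.0, degree: int = 2,
                 mu: float = 0.5, ridge: float = 0.1, weighted: bool = True,
                 view_split=None):
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.mu = mu
        self.ridge = ridge
        self.weighted = weighted
        self.view_split = view_split

    def _gram(self, Xa, Xb) -> np.ndarray:
        if self.kernel == "composited":
            if self.view_split is None:
                raise ValueError("composited kernel needs a view_split")
            v1, v2 = self.view_split
            return composited_kernel(Xa, Xb, v1, v2, mu=self.mu,
                                     gamma=self.gamma, degree=self.degree)
        return kernel_matrix(Xa, Xb, self.kernel, gamma=self.gamma, degree=self.degree)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=np.float64)
        elif self.weighted:
            w = class_weights(y)
        else:
            w = np.ones(y.size)
        if np.any(w <= 0):
            raise ValueError("sample weights must be positive")
        self.train_anchors_ = X
        omega = self._gram(X, X)
        T = _one_hot_pm1(y_idx, self.classes_.size)
        s = np.sqrt(w)
        A = s[:, None] * omega * s[None, :]
        A.flat[:: X.shape[0] + 1] += self.ridge
        self.output_weights_ = s[:, None] * np.linalg.solve(A, T * s[:, None])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "output_weights_")
        K = self._gram(np.asarray(X, dtype=np.float64), self.train_anchors_)
        return K @ self.output_weights_

    def predict(self, X):
        f = self.decision_function(X)
        return self.classes_[np.argmax(f, axis=1)]


def resolve_view_split(names: list[str], prefixes1=("time.", "dwt.", "eigen."),
                       prefixes2=("cep.", "freq.", "sparse.")) -> tuple[np.ndarray, np.ndarray]:
    """Split feature columns by name prefix into the composited kernel's two views.

    View 1 holds the contextual clip-aggregate descriptors, view 2 the
    spectral/cepstral ones; columns matching neither fall into view 2.
    """
    v1 = [i for i, n in enumerate(names) if n.startswith(prefixes1)]
    v2 = [i for i in range(len(names)) if i not in set(v1)]
    return np.asarray(v1, dtype=int), np.asarray(v2, dtype=int)
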