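"""Multinomial (softmax) classification head.

Probabilities are p(y = j | x) ∝ exp(θⱼᵀx) with θ a k×d matrix; the cost is
the negative average log-likelihood over the batch.  At θ = 0 the prediction
is uniform and the cost is exactly ln k.  Logits are shifted by their row
maximum before exponentiation, which leaves the probabilities unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .optimize import minimize

__all__ = [
    "softmax_probs",
    "softmax_predict",
    "softmax_cost_and_grad",
    "SoftmaxClassifier",
]


def softmax_probs(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise class probabilities for inputs ``X`` (n, d) and ``theta`` (k, d)."""
    X = np.atleast_2d(X)
    if X.shape[1] != theta.shape[1]:
        raise ValueError(f"input width {X.shape[1]} != theta width {theta.shape[1]}")
    logits = X @ theta.T
    logits -= logits.max(axis=1, keepdims=True)  # shift-invariant stabilization
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def softmax_predict(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Probability vector for a single input (ties at argmax resolve to the
    lowest index by numpy convention)."""
    return softmax_probs(theta, np.atleast_2d(x))[0]


def softmax_cost_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                          l2_weight: float = 0.0):
    """Negative mean log-likelihood and its gradient with respect to θ."""
    X = np.atleast_2d(X)
    y = np.asarray(y, dtype=int)
    m, d = X.shape
    if m == 0:
        raise ValueError("empty batch")
    k = theta.shape[0]
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    P = softmax_probs(theta, X)
    cost = -np.mean(np.log(np.clip(P[np.arange(m), y], 1e-300, None)))
    cost += 0.5 * l2_weight * np.sum(theta**2)
    Y = np.zeros_like(P)
    Y[np.arange(m), y] = 1.0
    grad = (P - Y).T @ X / m + l2_weight * theta
    return cost, grad


@dataclass
class SoftmaxClassifier:
    """Standalone softmax head trained full-batch (SCG by default)."""

    n_classes: int = 4
    fit_intercept: bool = True
    l2_weight: float = 0.0
    optimizer: str = "scg"
    max_iter: int = 1000
    theta_: Optional[np.ndarray] = None
    cost_history_: List[float] = field(default_factory=list)

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.fit_intercept:
            return np.hstack([X, np.ones((X.shape[0], 1))])
        return X

    def fit(self, X: np.ndarray, y: np.ndarray,
            theta0: Optional[np.ndarray] = None) -> "SoftmaxClassifier":
        Xd = self._design(X)
        k, d = self.n_classes, Xd.shape[1]
        if theta0 is None:
            theta0 = np.zeros((k, d))

        def fun(flat):
            c, g = softmax_cost_and_grad(flat.reshape(k, d), Xd, y, self.l2_weight)
            return c, g.ravel()

        res = minimize(fun, theta0.ravel(), method=self.optimizer,
                       max_iter=self.max_iter)
        self.theta_ = res.x.reshape(k, d)
        self.cost_history_ = res.cost_history
        return self

    @property
    def trained(self) -> bool:
        return self.theta_ is not None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("classifier not fitted")
        return softmax_probs(self.theta_, self._design(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
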