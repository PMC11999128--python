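"""Minimal feed-forward binary classifier.

Three fully connected hidden layers of 256 units with ReLU activations,
inverted dropout between layers, and a sigmoid output modeling the
transition probability. Trained with minibatch Adam on binary
cross-entropy plus L2 weight decay. The class follows the sklearn
estimator protocol (``fit`` / ``predict_proba`` / ``predict`` /
``get_params`` / ``set_params``) so it can sit in the same model grid
and cross-validation loops as the other learners. Continuous features
should be standardized upstream (the training pipeline wraps it in a
``StandardScaler``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


class TrainingDivergedError(FloatingPointError):
    """Loss became non-finite during training."""


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class FeedForwardClassifier(ClassifierMixin, BaseEstimator):
    """3x256 ReLU network with dropout and a sigmoid output."""

    def __init__(
        self,
        hidden_units: int = 256,
        n_hidden: int = 3,
        dropout: float = 0.2,
        l2: float = 1e-4,
        learning_rate: float = 1e-3,
        epochs: int = 30,
        batch_size: int = 64,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.n_hidden = n_hidden
        self.dropout = dropout
        self.l2 = l2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # get_params / set_params / sklearn tags come from BaseEstimator

    # -- training -----------------------------------------------------------

    def _init_weights(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features] + [self.hidden_units] * self.n_hidden + [1]
        self._weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self._biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, list]:
        cache = []
        a = X
        for layer in range(self.n_hidden):
            z = a @ self._weights[layer] + self._biases[layer]
            h = _relu(z)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            else:
                mask = None
            cache.append((a, z, mask))
            a = h
        z_out = a @ self._weights[-1] + self._biases[-1]
        # numerically safe sigmoid
        p = np.where(
            z_out >= 0, 1.0 / (1.0 + np.exp(-z_out)), np.exp(z_out) / (1.0 + np.exp(z_out))
        )
        cache.append((a, z_out, None))
        return p.ravel(), cache

    def fit(self, X, y) -> "FeedForwardClassifier":
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)
        self._init_weights(X.shape[1], rng)
        self.classes_ = np.array([0, 1])

        # Adam state
        m_w = [np.zeros_like(w) for w in self._weights]
        v_w = [np.zeros_like(w) for w in self._weights]
        m_b = [np.zeros_like(b) for b in self._biases]
        v_b = [np.zeros_like(b) for b in self._biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(X)
        batch = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb, yb = X[idx], y[idx]
                p, cache = self._forward(xb, rng)
                if not np.all(np.isfinite(p)):
                    raise TrainingDivergedError(
                        f"non-finite activations at step {t}; "
                        f"lr={self.learning_rate}, l2={self.l2}"
                    )
                # d(BCE)/dz_out = p - y  (mean over batch)
                delta = ((p - yb) / len(xb))[:, None]
                grads_w, grads_b = [], []
                for layer in range(self.n_hidden, -1, -1):
                    a_in, z, mask = cache[layer]
                    grads_w.append(a_in.T @ delta + self.l2 * self._weights[layer])
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = delta @ self._weights[layer].T
                        _, z_prev, mask_prev = cache[layer - 1]
                        if mask_prev is not None:
                            delta = delta * mask_prev
                        delta = delta * (z_prev > 0)
                grads_w.reverse()
                grads_b.reverse()
                t += 1
                for layer in range(len(self._weights)):
                    for grad, mom, vel, param in (
                        (grads_w[layer], m_w, v_w, self._weights),
                        (grads_b[layer], m_b, v_b, self._biases),
                    ):
                        mom[layer] = beta1 * mom[layer] + (1 - beta1) * grad
                        vel[layer] = beta2 * vel[layer] + (1 - beta2) * grad**2
                        m_hat = mom[layer] / (1 - beta1**t)
                        v_hat = vel[layer] / (1 - beta2**t)
                        param[layer] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p, _ = self._forward(X, rng=None)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
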