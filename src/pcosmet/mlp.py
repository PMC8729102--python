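"""Single-hidden-layer backprop classifier with sigmoid or sine hidden units.

This is the fitness learner inside the evolutionary feature-selection loop and
the final predictive model.  Two presets mirror the architectures used for the
response-prediction experiments: a standard backprop net with 4 hidden units
(``FF_BP``) and a sine-activation net with 8 hidden units (``SINE_NET``).

Training is deterministic full-batch gradient descent with momentum on the
cross-entropy loss; inputs are standardized internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["MLPSpec", "BackpropClassifier", "train_mlp", "FF_BP", "SINE_NET"]


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and optimisation settings of the classifier."""

    hidden_units: int = 4
    activation: str = "sigmoid"  # "sigmoid" | "sine"
    learning_rate: float = 0.5
    epochs: int = 300
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in ("sigmoid", "sine"):
            raise ValueError("activation must be 'sigmoid' or 'sine'")


#: Backprop preset: 4 hidden sigmoid units.
FF_BP = MLPSpec(hidden_units=4, activation="sigmoid")
#: Sine-net preset: 8 hidden units with elementwise sine activation.
SINE_NET = MLPSpec(hidden_units=8, activation="sine")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BackpropClassifier:
    """Binary classifier y ∈ {0,1} with one hidden layer."""

    def __init__(self, spec: Optional[MLPSpec] = None):
        self.spec = spec if spec is not None else MLPSpec()
        self._fitted = False

    def fit(self, X, y) -> "BackpropClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with rows matching y")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        if len(classes) < 2:
            raise ValueError("y contains a single class; cannot train a classifier")

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (X - self._mu) / self._sd

        n, p = Z.shape
        h = self.spec.hidden_units
        rng = np.random.default_rng(self.spec.seed)
        scale1 = 1.0 / np.sqrt(p)
        self.W1 = rng.uniform(-scale1, scale1, size=(p, h))
        self.b1 = np.zeros(h)
        scale2 = 1.0 / np.sqrt(h)
        self.w2 = rng.uniform(-scale2, scale2, size=h)
        self.b2 = 0.0

        vW1 = np.zeros_like(self.W1)
        vb1 = np.zeros_like(self.b1)
        vw2 = np.zeros_like(self.w2)
        vb2 = 0.0
        lr, mom = self.spec.learning_rate, self.spec.momentum
        sine = self.spec.activation == "sine"

        for _ in range(self.spec.epochs):
            pre = Z @ self.W1 + self.b1
            a = np.sin(pre) if sine else _sigmoid(pre)
            prob = _sigmoid(a @ self.w2 + self.b2)
            err = (prob - y) / n                       # dL/dz2 for cross-entropy
            gw2 = a.T @ err
            gb2 = err.sum()
            da = np.outer(err, self.w2)
            dpre = da * (np.cos(pre) if sine else a * (1.0 - a))
            gW1 = Z.T @ dpre
            gb1 = dpre.sum(axis=0)

            vW1 = mom * vW1 - lr * gW1
            vb1 = mom * vb1 - lr * gb1
            vw2 = mom * vw2 - lr * gw2
            vb2 = mom * vb2 - lr * gb2
            self.W1 += vW1
            self.b1 += vb1
            self.w2 += vw2
            self.b2 += vb2
        self._fitted = True
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier is not fitted")
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        pre = Z @ self.W1 + self.b1
        a = np.sin(pre) if self.spec.activation == "sine" else _sigmoid(pre)
        return _sigmoid(a @ self.w2 + self.b2)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def score(self, X, y) -> float:
        """Classification accuracy."""
        y = np.asarray(y).ravel()
        return float((self.predict(X) == y).mean())


def train_mlp(X, y, spec: Optional[MLPSpec] = None) -> BackpropClassifier:
    """Fit a :class:`BackpropClassifier` and return it."""
    return BackpropClassifier(spec).fit(X, y)
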