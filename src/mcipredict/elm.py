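"""Kernel extreme learning machine and reference baseline classifiers.

The kernel ELM solves, in closed form,

    beta = (Omega + I / C)^{-1} y,    Omega_ij = K(x_i, x_j)

with an RBF kernel K(a, b) = exp(-gamma * ||a - b||^2) and predicts new
points by f(x) = [K(x, x_1) ... K(x, x_N)] beta.  For C > 0 the system
is symmetric positive definite, so a Cholesky solve always succeeds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from mcipredict.io import FeatureMatrix

DEFAULT_REG_C = 1.0


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


@dataclasses.dataclass
class ElmModel:
    train_features: np.ndarray
    train_labels: np.ndarray  # {+1, -1}
    kernel_gamma: float
    reg_C: float
    beta: np.ndarray

    @classmethod
    def solve(
        cls, X: np.ndarray, y: np.ndarray, gamma: float, reg_C: float
    ) -> "ElmModel":
        """Closed-form solve without class-balance guards (low level)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (N, d) with one label per row")
        if reg_C <= 0 or gamma <= 0:
            raise ValueError("gamma and reg_C must be positive")
        omega = rbf_kernel(X, X, gamma)
        A = omega + np.eye(len(y)) / reg_C
        beta = cho_solve(cho_factor(A, lower=True), y)
        return cls(X, y, gamma, reg_C, beta)


def train_elm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    gamma: float | None = None,
    reg_C: float = DEFAULT_REG_C,
) -> ElmModel:
    """Train the kernel ELM; requires N >= 2 and both classes present.

    ``gamma`` defaults to 1/d on (assumed standardized) features.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=float)
    y = np.where(y > 0, 1.0, -1.0)
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    return ElmModel.solve(X, y, gamma, reg_C)


def elm_decision(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Continuous score k(x)^T beta for each row of X (ROC input)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model's {model.train_features.shape[1]}"
        )
    return rbf_kernel(X, model.train_features, model.kernel_gamma) @ model.beta


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Binary {+1, -1} labels, threshold at 0 (ties to +1)."""
    return np.where(elm_decision(model, X) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# classifier adapters (common fit/decision interface for the CV harness)


class ElmClassifier:
    """Adapter exposing fit/decision for the evaluation harness."""

    def __init__(self, gamma: float | None = None, reg_C: float = DEFAULT_REG_C):
        self.gamma, self.reg_C = gamma, reg_C
        self.model: ElmModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ElmClassifier":
        self.model = train_elm(X, y, gamma=self.gamma, reg_C=self.reg_C)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        assert self.model is not None, "classifier not fitted"
        return elm_decision(self.model, X)


class SvmClassifier:
    """RBF support vector machine baseline."""

    def __init__(self, C: float = 1.0, gamma: str | float = "scale", seed: int = 0):
        self._clf = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)

    def fit(self, X, y):
        self._clf.fit(X, np.asarray(y))
        return self

    def decision(self, X) -> np.ndarray:
        return self._clf.decision_function(X)


class RandomForestBaseline:
    """Random forest baseline; decision = P(positive) - 0.5."""

    def __init__(self, n_estimators: int = 200, seed: int = 0):
        self._clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)

    def fit(self, X, y):
        self._clf.fit(X, np.asarray(y))
        return self

    def decision(self, X) -> np.ndarray:
        pos = list(self._clf.classes_).index(max(self._clf.classes_))
        return self._clf.predict_proba(X)[:, pos] - 0.5


CLASSIFIERS = {
    "elm": ElmClassifier,
    "svm": SvmClassifier,
    "rf": RandomForestBaseline,
}
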