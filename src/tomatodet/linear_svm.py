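"""Soft-margin linear SVM with margin-to-probability calibration.

The classifier is the standard hinge-loss soft-margin SVM (penalty C = 1 by
default), solved exactly via libsvm's dual solver. The sliding-window scanner
needs a confidence in [0, 1] for non-maximum suppression, so a Platt-style
logistic calibration is fitted on held-out decision margins. The logistic has
no intercept — confidence is sigmoid(A * margin) with A > 0 — which pins
confidence 0.5 to the decision boundary and keeps it monotone in the margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.svm import SVC

__all__ = ["LinearModel", "train", "predict", "decision_function", "confidence"]


@dataclass
class LinearModel:
    """Weight-vector + bias separator with optional probability calibration."""

    weights: np.ndarray
    bias: float
    C: float = 1.0
    calibration_scale: Optional[float] = None  # A in sigmoid(A * margin)
    hog_config_hash: Optional[str] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("model parameters must be finite")
        if self.C <= 0:
            raise ValueError("C must be positive")

    @property
    def is_calibrated(self) -> bool:
        return self.calibration_scale is not None


def _validate_training(X: np.ndarray, y: np.ndarray) -> None:
    labels = np.unique(y)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be in {+1, -1}")
    if labels.size < 2:
        raise ValueError("training requires both classes")
    if X.shape[0] != y.shape[0]:
        raise ValueError("vectors and labels disagree in length")


def _fit_linear(X: np.ndarray, y: np.ndarray, C: float, tol: float):
    """Exact soft-margin linear SVM via libsvm on a precomputed Gram matrix.

    The Gram matrix goes through BLAS, which is far faster in high feature
    dimensions than libsvm's own kernel evaluations; the solution is the
    same dual optimum. Returns (w, b) oriented so +1 is the positive side.
    """
    gram = X @ X.T
    svc = SVC(kernel="precomputed", C=C, tol=tol, shrinking=True, cache_size=500)
    svc.fit(gram, y)
    w = (svc.dual_coef_ @ X[svc.support_]).ravel()
    b = float(svc.intercept_[0])
    if svc.classes_[1] != 1:
        w, b = -w, -b
    return w, b


def _platt_scale(margins: np.ndarray, y: np.ndarray) -> float:
    """MLE of A in P(y=+1|m) = sigmoid(A*m), with Platt's smoothed targets.

    The smoothed targets (N+ + 1)/(N+ + 2) and 1/(N- + 2) keep the estimate
    finite when the held-out margins are perfectly separated.
    """
    n_pos = int(np.sum(y > 0))
    n_neg = int(np.sum(y < 0))
    t = np.where(y > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(log_a: float) -> float:
        a = np.exp(log_a)
        z = np.clip(a * margins, -500, 500)
        # cross-entropy of sigmoid(z) against smoothed targets
        return float(np.sum(np.logaddexp(0.0, -z) + (1.0 - t) * z))

    res = minimize_scalar(nll, bounds=(-10.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    calibrate: bool = True,
    calibration_frac: float = 0.25,
    tol: float = 1e-6,
    rng_seed: int = 0,
) -> LinearModel:
    """Train the soft-margin linear SVM, optionally with Platt calibration.

    Calibration fits the logistic scale on the margins of a held-out,
    stratified fraction of the data, then the final separator is refit on
    all samples. With ``calibrate=False`` the model has no confidence map
    (``confidence`` will refuse it).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64).ravel()
    _validate_training(X, y)

    scale: Optional[float] = None
    if calibrate:
        rng = np.random.default_rng(rng_seed)
        hold = np.zeros(len(y), dtype=bool)
        for cls in (-1, 1):
            idx = np.flatnonzero(y == cls)
            n_hold = max(1, int(round(calibration_frac * idx.size)))
            hold[rng.choice(idx, size=n_hold, replace=False)] = True
        if np.unique(y[~hold]).size < 2:
            raise ValueError("too few samples per class to calibrate")
        w_part, b_part = _fit_linear(X[~hold], y[~hold], C, tol)
        margins = X[hold] @ w_part + b_part
        scale = _platt_scale(margins, y[hold])

    w, b = _fit_linear(X, y, C, tol)
    return LinearModel(weights=w, bias=b, C=C, calibration_scale=scale)


def decision_function(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Signed margin w.x + b for one vector or a (N, D) stack."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None]
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.weights.size}"
        )
    m = X @ model.weights + model.bias
    return m[0] if single else m


def predict(model: LinearModel, X: np.ndarray):
    """sign(w.x + b) with the tie (margin exactly 0) resolved to +1."""
    m = decision_function(model, X)
    if np.ndim(m) == 0:
        return 1 if m >= 0 else -1
    return np.where(m >= 0, 1, -1)


def confidence(model: LinearModel, X: np.ndarray):
    """Calibrated probability of the tomato class; 0.5 at margin 0."""
    if not model.is_calibrated:
        raise ValueError("model has no calibration; train with calibrate=True")
    m = decision_function(model, X)
    z = np.clip(model.calibration_scale * np.asarray(m, dtype=np.float64), -500, 500)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p) if np.ndim(m) == 0 else p


def hinge_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Primal objective 0.5||w||^2 + C * sum(max(0, 1 - y(w.x+b))).

    Exposed so independent solvers can be compared on equal terms.
    """
    w = np.asarray(w, dtype=np.float64).ravel()
    slack = np.maximum(0.0, 1.0 - y * (X @ w + b))
    return 0.5 * float(w @ w) + C * float(slack.sum())
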