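"""Kernel extreme learning machine (KELM) with an RBF kernel.

A KELM replaces the random hidden layer of an extreme learning machine
with a kernel, so training reduces to one regularised symmetric linear
solve: with kernel matrix Ω (Ω_ij = K(x_i, x_j)) and one-hot targets Y,
the dual coefficients A solve (Ω + I/C) A = Y and new points are scored
as K(X_new, X) A. The RBF kernel follows the γ² convention
K(x, z) = exp(-||x - z||² / γ²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

__all__ = ["KernelSettings", "KELMModel", "rbf_kernel", "kelm_train", "kelm_predict"]


@dataclass(frozen=True)
class KernelSettings:
    """RBF width ``gamma`` and regularisation factor ``C`` (both > 0)."""

    gamma: float = 1.0
    C: float = 32.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class KELMModel:
    """Fitted model: stored training inputs, classes and dual coefficients."""

    X: np.ndarray
    classes: np.ndarray
    dual_coef: np.ndarray  # (n_train, n_classes), solves (Ω + I/C) A = Y
    settings: KernelSettings


def rbf_kernel(X: np.ndarray, Z: np.ndarray, gamma: float) -> np.ndarray:
    """Gram matrix exp(-||x_i - z_j||² / γ²) between rows of X and Z."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("feature dimension mismatch")
    sq = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-sq / gamma**2)


def kelm_train(X: np.ndarray, labels, settings: KernelSettings) -> KELMModel:
    """Fit the KELM by the closed-form regularised solve.

    Labels are one-hot encoded over their sorted unique values; the
    system (Ω + I/C) A = Y is solved symmetrically (never by explicit
    inversion), with a tiny diagonal jitter retry for near-singular
    Gram matrices (duplicate rows at large C).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("X and labels length mismatch")
    classes, idx = np.unique(labels, return_inverse=True)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    Y = np.zeros((X.shape[0], classes.shape[0]))
    Y[np.arange(X.shape[0]), idx] = 1.0

    omega = rbf_kernel(X, X, settings.gamma)
    system = omega + np.eye(X.shape[0]) / settings.C
    try:
        A = solve(system, Y, assume_a="pos")
    except np.linalg.LinAlgError:
        A = solve(system + 1e-12 * np.eye(X.shape[0]), Y, assume_a="pos")
    return KELMModel(X=X, classes=classes, dual_coef=A, settings=settings)


def kelm_predict(model: KELMModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class scores for new rows.

    Scores are K(X_new, X) A; the predicted class is the argmax over
    one-hot columns, with ties resolved toward the lexicographically
    smaller class label (classes are stored sorted, argmax takes the
    first maximum).
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.X.shape[1]:
        raise ValueError("feature dimension mismatch with training data")
    scores = rbf_kernel(Xnew, model.X, model.settings.gamma) @ model.dual_coef
    labels = model.classes[np.argmax(scores, axis=1)]
    return labels, scores
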