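"""Precomputed-kernel SVM training and the three baseline kernels.

The quadratic-programming solver itself is an external contract
(``sklearn.svm.SVC``); this module owns the precomputed-Gram calling
convention, the linear / polynomial / RBF baseline kernels, and decision
scores (signed hyperplane distances) for ROC analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel
from sklearn.svm import SVC

from .evaluation import MetricsReport, metrics
from .kernel_lang import GramMatrix

__all__ = [
    "SVMConfig",
    "TrainedModel",
    "resolve_gamma",
    "baseline_gram",
    "train_precomputed",
    "train_eval_precomputed",
]


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin SVM hyperparameters.

    ``gamma``/``degree``/``coef0`` only matter for the RBF and polynomial
    baselines; a precomputed evolved kernel has no such hyperparameters
    (that independence is the point of evolving the kernel).  ``gamma`` may
    be the ``"scale"`` convention, 1 / (d * var(X)), resolved against the
    training matrix.
    """

    C: float = 1.0
    kernel_kind: str = "precomputed"
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 0.0
    class_weight: Optional[str] = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel_kind not in ("precomputed", "linear", "rbf", "poly"):
            raise ValueError(f"unknown kernel kind {self.kernel_kind!r}")
        if not (self.gamma == "scale" or (
            isinstance(self.gamma, (int, float)) and self.gamma > 0
        )):
            raise ValueError("gamma must be positive or 'scale'")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def resolve_gamma(gamma, X: np.ndarray) -> float:
    """Resolve the ``"scale"`` convention against a training matrix."""
    if gamma == "scale":
        var = float(X.var())
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma must be positive")
    return g


def baseline_gram(kind: str, A, B=None, cfg: Optional[SVMConfig] = None) -> GramMatrix:
    """Gram matrix of a baseline kernel: K(A_i, B_j); ``B`` defaults to ``A``.

    linear: <a, b>; poly: (gamma <a, b> + coef0)^degree;
    rbf: exp(-gamma ||a - b||^2).  gamma is resolved on ``B`` (the training
    side in the rectangular test-vs-train case).
    """
    cfg = cfg if cfg is not None else SVMConfig(kernel_kind=kind)
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-d with a shared feature dimension")
    if kind == "linear":
        K = linear_kernel(A, B)
    elif kind == "rbf":
        K = rbf_kernel(A, B, gamma=resolve_gamma(cfg.gamma, B))
    elif kind == "poly":
        K = polynomial_kernel(
            A, B, degree=cfg.degree, gamma=resolve_gamma(cfg.gamma, B),
            coef0=cfg.coef0,
        )
    else:
        raise ValueError(f"unknown baseline kernel {kind!r}")
    return GramMatrix(np.asarray(K, dtype=float))


@dataclass
class TrainedModel:
    """A fitted precomputed-kernel SVM plus its support-vector indices."""

    svc: SVC
    support_indices: np.ndarray
    train_accuracy: float

    def decision_function(self, G_test: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(G_test)

    def predict(self, G_test: np.ndarray) -> np.ndarray:
        return self.svc.predict(G_test)


def _check_train_gram(G_train: GramMatrix, y_train: np.ndarray) -> np.ndarray:
    K = G_train.values
    if K.shape[0] != K.shape[1]:
        raise ValueError("training Gram must be square")
    if K.shape[0] != len(y_train):
        raise ValueError("training Gram and labels disagree in length")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("training Gram must be symmetric; repair it first")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    return K


def train_precomputed(G_train: GramMatrix, y_train, cfg: Optional[SVMConfig] = None) -> TrainedModel:
    """Fit a soft-margin SVM on a (repaired) precomputed training Gram."""
    cfg = cfg if cfg is not None else SVMConfig()
    y_train = np.asarray(y_train)
    K = _check_train_gram(G_train, y_train)
    svc = SVC(C=cfg.C, kernel="precomputed", class_weight=cfg.class_weight)
    svc.fit(K, y_train)
    train_acc = float(np.mean(svc.predict(K) == y_train))
    return TrainedModel(svc, svc.support_.copy(), train_acc)


def train_eval_precomputed(
    G_train: GramMatrix,
    y_train,
    G_test: GramMatrix,
    y_test,
    cfg: Optional[SVMConfig] = None,
) -> MetricsReport:
    """Train on ``G_train`` and score the held-out ``G_test`` block.

    ``G_test`` rows are test samples, columns align with training rows.
    The returned report carries the decision scores in a private
    ``_scores`` attribute for ROC pooling.
    """
    y_test = np.asarray(y_test)
    if G_test.values.shape[1] != G_train.values.shape[0]:
        raise ValueError("G_test columns must align with training rows")
    if G_test.values.shape[0] != len(y_test):
        raise ValueError("G_test rows and y_test disagree in length")
    model = train_precomputed(G_train, y_train, cfg)
    scores = model.decision_function(G_test.values)
    y_pred = model.predict(G_test.values)
    report = metrics(y_test, scores, y_pred)
    report._scores = scores  # type: ignore[attr-defined]
    return report
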