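"""Linear soft-margin SVM base learner.

The base learner minimizes the L2-regularized, class-weighted hinge
loss (exact dual solution via libsvm).  Decision scores are geometric:
(w.x + b) / ||w||, the signed distance from the separating hyperplane,
with the patient (case) group on the positive side.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "LinearModel",
    "train_svm",
    "decision_values",
    "predict_labels",
    "tune_C",
    "balanced_accuracy",
    "DEFAULT_C_GRID",
]

#: default regularization grid: 11 powers of two spanning under- to
#: over-regularized regimes
DEFAULT_C_GRID = tuple(float(2.0**p) for p in range(-6, 5))

SOLVER_TOL = 1e-6


class TrainingError(ValueError):
    """The classifier cannot be trained on the given data."""


@dataclasses.dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    regularization_C: float
    class_weights: dict[int, float]
    selected_features: np.ndarray  # column indices the model was trained on

    def __post_init__(self) -> None:
        if self.regularization_C <= 0:
            raise ValueError("C must be positive")
        if len(self.weights) != len(self.selected_features):
            raise ValueError("weight vector length must equal selected-feature count")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "regularization_C": self.regularization_C,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "selected_features": self.selected_features.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            regularization_C=float(d["regularization_C"]),
            class_weights={int(k): float(v) for k, v in d["class_weights"].items()},
            selected_features=np.asarray(d["selected_features"], dtype=int),
        )


def inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    """Class weights proportional to inverse class frequency (mean 1)."""
    y = np.asarray(y)
    n = len(y)
    return {int(c): n / (2.0 * np.sum(y == c)) for c in (-1, 1)}


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    class_weights: dict[int, float] | None = None,
    selected_features: np.ndarray | None = None,
) -> LinearModel:
    """Fit the weighted linear SVM; deterministic up to solver tolerance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise TrainingError("feature matrix contains missing values")
    classes = np.unique(y)
    if classes.size != 2:
        raise TrainingError(f"need both classes present, got {classes.tolist()}")
    if class_weights is None:
        class_weights = inverse_frequency_weights(y)
    clf = SVC(kernel="linear", C=C, class_weight=class_weights, tol=SOLVER_TOL)
    clf.fit(X, y)
    # sklearn orders classes ascending, so coef_ points toward +1 (cases)
    w = np.asarray(clf.coef_[0], dtype=float)
    b = float(clf.intercept_[0])
    if selected_features is None:
        selected_features = np.arange(X.shape[1])
    return LinearModel(w, b, float(C), class_weights, np.asarray(selected_features, dtype=int))


def decision_values(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Geometric decision scores (w.x + b)/||w||; positive side = case."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else 'bad'} columns, "
            f"model expects {len(model.weights)}"
        )
    raw = X @ model.weights + model.bias
    norm = float(np.linalg.norm(model.weights))
    return raw / norm if norm > 0 else raw


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """Sign rule: score > 0 -> case (+1), otherwise control (-1)."""
    return np.where(np.asarray(scores) > 0, 1, -1)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of sensitivity and specificity, on the [0, 1] scale."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == -1
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy needs both classes in the truth")
    sens = np.mean(y_pred[pos] == 1)
    spec = np.mean(y_pred[neg] == -1)
    return float((sens + spec) / 2.0)


def tune_C(
    fit_sets: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    grid: Sequence[float] = DEFAULT_C_GRID,
    class_weights: dict[int, float] | None = None,
) -> float:
    """Pick the grid value maximizing mean validation balanced accuracy.

    ``fit_sets`` are (X_train, y_train, X_val, y_val) splits from the
    inner CV cycle.  Ties are broken toward the smaller C.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("C grid must be nonempty")
    best_c, best_score = None, -np.inf
    for c in sorted(grid):
        scores = []
        for Xtr, ytr, Xval, yval in fit_sets:
            model = train_svm(Xtr, ytr, c, class_weights)
            scores.append(balanced_accuracy(yval, predict_labels(decision_values(model, Xval))))
        mean = float(np.mean(scores))
        if mean > best_score:  # strict: earlier (smaller) C wins ties
            best_c, best_score = c, mean
    return float(best_c)
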