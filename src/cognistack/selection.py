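"""Greedy forward-search wrapper feature selection.

The wrapper starts from the empty set and, at each step, adds the
feature whose inclusion maximizes validation balanced accuracy of a
retrained linear SVM, stopping as soon as no candidate strictly
improves the score (or a feature budget is reached).  The first
feature is always added so that every base model is nonempty.  Ties
are broken toward the lower feature index, which makes the trace fully
deterministic.

Selection probabilities aggregate final masks over all base models of
a cross-validation ensemble: the probability of a feature is simply
the fraction of base models whose mask contains it.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .svm import balanced_accuracy, decision_values, predict_labels, train_svm

__all__ = [
    "SelectionTrace",
    "SelectionProbabilities",
    "greedy_forward_select",
    "aggregate_selection_probabilities",
]

FitSets = Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]


@dataclasses.dataclass
class SelectionTrace:
    ordered_added_features: list[int]
    score_after_each_add: list[float]

    @property
    def final_mask(self) -> np.ndarray:
        return np.asarray(self.ordered_added_features, dtype=int)

    def to_dict(self) -> dict:
        return {
            "ordered_added_features": [int(i) for i in self.ordered_added_features],
            "score_after_each_add": [float(s) for s in self.score_after_each_add],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionTrace":
        return cls(list(d["ordered_added_features"]), list(d["score_after_each_add"]))


@dataclasses.dataclass
class SelectionProbabilities:
    feature_names: tuple[str, ...]
    probabilities: np.ndarray
    n_models: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "probability": self.probabilities}
        )

    def report(self, threshold: float = 0.5) -> pd.DataFrame:
        """Figure-style report: features above threshold, most likely first."""
        frame = self.as_frame()
        return (
            frame[frame["probability"] > threshold]
            .sort_values("probability", ascending=False)
            .reset_index(drop=True)
        )


def _score_mask(
    mask: list[int],
    fit_sets: FitSets,
    C: float,
    class_weights: dict[int, float] | None,
) -> float:
    scores = []
    for Xtr, ytr, Xval, yval in fit_sets:
        model = train_svm(Xtr[:, mask], ytr, C, class_weights)
        scores.append(balanced_accuracy(yval, predict_labels(decision_values(model, Xval[:, mask]))))
    return float(np.mean(scores))


def greedy_forward_select(
    fit_sets: FitSets,
    C: float,
    class_weights: dict[int, float] | None = None,
    max_features: int | None = None,
) -> SelectionTrace:
    """Forward search over the columns of the given train/validation splits.

    ``fit_sets`` holds one or more (X_train, y_train, X_val, y_val)
    splits; candidate subsets are scored by mean validation balanced
    accuracy over them.  Only the rows inside these splits are ever
    read, so leakage is impossible by construction.
    """
    if not fit_sets:
        raise ValueError("at least one train/validation split is required")
    n_features = fit_sets[0][0].shape[1]
    if n_features < 1:
        raise ValueError("at least one candidate feature is required")
    if max_features is None:
        max_features = n_features
    max_features = min(max_features, n_features)

    added: list[int] = []
    scores: list[float] = []
    best = -np.inf
    remaining = list(range(n_features))
    while len(added) < max_features and remaining:
        cand_scores = [_score_mask(added + [j], fit_sets, C, class_weights) for j in remaining]
        k = int(np.argmax(cand_scores))  # argmax takes the first max: lower index wins ties
        if added and cand_scores[k] <= best:
            break
        added.append(remaining.pop(k))
        best = max(best, cand_scores[k])
        scores.append(cand_scores[k])
    return SelectionTrace(added, scores)


def aggregate_selection_probabilities(
    masks: Iterable[np.ndarray], feature_names: Sequence[str]
) -> SelectionProbabilities:
    """Per-feature selection frequency across base-model masks."""
    counts = np.zeros(len(feature_names))
    n_models = 0
    for mask in masks:
        counts[np.asarray(mask, dtype=int)] += 1
        n_models += 1
    if n_models == 0:
        raise ValueError("no base models supplied")
    return SelectionProbabilities(tuple(feature_names), counts / n_models, n_models)
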