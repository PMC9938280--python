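"""Repeated, double-cycle nested cross-validation engine.

Design.  The outer cycle (CV2) estimates generalization only: its test
folds never influence any fitted quantity.  For each outer partition
(one fold of one repetition) an inner cycle (CV1) is built on the
outer-training subjects.  Each CV1 partition contributes one base
model: preprocessing is fitted on the CV1-training subjects, the
regularization constant is tuned once per outer partition on the CV1
splits, and a greedy forward wrapper selects that base model's feature
subset against its CV1 validation fold.  With the default 10 folds x 5
repetitions this yields the classical ensemble of 50 base models per
outer partition.  Outer-test subjects are predicted by majority vote
across the ensemble, with the mean geometric decision value as the
subject's score; records aggregate across outer repetitions, so every
subject receives exactly ``outer_repetitions`` out-of-training
predictions.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .data import SubjectTable
from .metrics import MetricsReport, compute_metrics
from .preprocess import PreprocessModel, apply_preprocess, fit_preprocess
from .selection import SelectionTrace, greedy_forward_select
from .svm import LinearModel, decision_values, train_svm, tune_C

__all__ = [
    "CVScheme",
    "BaseModel",
    "EnsembleModel",
    "NestedCVResult",
    "make_cv_scheme",
    "majority_vote",
    "run_nested_cv",
]


@dataclasses.dataclass
class CVScheme:
    """Stratified fold assignments for every repetition.

    ``assignments[r, i]`` is the fold index of subject ``i`` in
    repetition ``r``; within a repetition the folds partition the
    cohort and per-fold class counts are within one of perfect
    stratification.
    """

    n_folds: int
    n_repetitions: int
    seed: int
    assignments: np.ndarray

    def test_indices(self, repetition: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repetition] == fold)

    def train_indices(self, repetition: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repetition] != fold)


def make_cv_scheme(
    labels: np.ndarray, n_folds: int, n_repetitions: int, seed: int
) -> CVScheme:
    """Build stratified folds, re-shuffling subjects within their groups
    for every repetition; deterministic under ``seed``."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than {n_folds} folds"
        )
    rng = np.random.SeedSequence(seed)
    assignments = np.empty((n_repetitions, len(labels)), dtype=int)
    for r, child in enumerate(rng.spawn(n_repetitions)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for fold, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignments[r, test] = fold
    return CVScheme(n_folds, n_repetitions, seed, assignments)


def majority_vote(votes: Sequence[int], scores: Sequence[float]) -> int:
    """Most frequent label; ties resolved by the sign of the mean decision
    score, with a zero mean falling to the control label."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("cannot vote with no votes")
    pos = int(np.sum(votes == 1))
    neg = int(np.sum(votes == -1))
    if pos != neg:
        return 1 if pos > neg else -1
    return 1 if float(np.mean(scores)) > 0 else -1


@dataclasses.dataclass
class BaseModel:
    """One CV1-partition model: frozen preprocessing + trained SVM."""

    preprocess: PreprocessModel
    model: LinearModel
    trace: SelectionTrace
    inner_repetition: int
    inner_fold: int
    inner_train_idx: np.ndarray  # global row indices into the discovery table
    inner_test_idx: np.ndarray

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "model": self.model.to_dict(),
            "trace": self.trace.to_dict(),
            "inner_repetition": self.inner_repetition,
            "inner_fold": self.inner_fold,
            "inner_train_idx": self.inner_train_idx.tolist(),
            "inner_test_idx": self.inner_test_idx.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaseModel":
        return cls(
            preprocess=PreprocessModel.from_dict(d["preprocess"]),
            model=LinearModel.from_dict(d["model"]),
            trace=SelectionTrace.from_dict(d["trace"]),
            inner_repetition=int(d["inner_repetition"]),
            inner_fold=int(d["inner_fold"]),
            inner_train_idx=np.asarray(d["inner_train_idx"], dtype=int),
            inner_test_idx=np.asarray(d["inner_test_idx"], dtype=int),
        )


@dataclasses.dataclass
class EnsembleModel:
    """All base models of one outer (CV2) partition."""

    modality: str
    outer_repetition: int
    outer_fold: int
    outer_train_idx: np.ndarray
    outer_test_idx: np.ndarray
    regularization_C: float
    base_models: list[BaseModel]
    feature_names: tuple[str, ...]

    def masks(self) -> list[np.ndarray]:
        return [b.trace.final_mask for b in self.base_models]

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "outer_repetition": self.outer_repetition,
            "outer_fold": self.outer_fold,
            "outer_train_idx": self.outer_train_idx.tolist(),
            "outer_test_idx": self.outer_test_idx.tolist(),
            "regularization_C": self.regularization_C,
            "base_models": [b.to_dict() for b in self.base_models],
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            modality=d["modality"],
            outer_repetition=int(d["outer_repetition"]),
            outer_fold=int(d["outer_fold"]),
            outer_train_idx=np.asarray(d["outer_train_idx"], dtype=int),
            outer_test_idx=np.asarray(d["outer_test_idx"], dtype=int),
            regularization_C=float(d["regularization_C"]),
            base_models=[BaseModel.from_dict(b) for b in d["base_models"]],
            feature_names=tuple(d["feature_names"]),
        )


@dataclasses.dataclass
class _PartitionCache:
    """Training-time matrices kept so permutation reruns need not redo
    the (label-free) preprocessing.  Never serialized."""

    inner_train_X: list[np.ndarray]  # preprocessed CV1-training matrices (all features)
    outer_test_X: list[np.ndarray]  # per base model: preprocessed outer-test matrices


@dataclasses.dataclass
class NestedCVResult:
    modality: str
    ensembles: list[EnsembleModel]
    records: pd.DataFrame  # subject_id, decision_score, voted_label, true_label, n_votes
    metrics: MetricsReport
    outer_scheme: CVScheme
    caches: list[_PartitionCache] | None = None


def aggregate_records(
    subject_ids: np.ndarray,
    y_true: np.ndarray,
    vote_pos: np.ndarray,
    vote_neg: np.ndarray,
    score_sum: np.ndarray,
) -> pd.DataFrame:
    n_votes = vote_pos + vote_neg
    mean_score = np.divide(score_sum, n_votes, out=np.zeros_like(score_sum), where=n_votes > 0)
    voted = np.where(
        vote_pos != vote_neg, np.where(vote_pos > vote_neg, 1, -1), np.where(mean_score > 0, 1, -1)
    )
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "decision_score": mean_score,
            "voted_label": voted,
            "true_label": y_true,
            "n_votes": n_votes.astype(int),
        }
    )


def run_nested_cv(
    table: SubjectTable,
    modality: str,
    config: PipelineConfig,
    keep_cache: bool = True,
) -> NestedCVResult:
    """Run the full double-cycle repeated nested CV for one modality.

    All model fitting — preprocessing, C tuning, wrapper selection,
    SVM training — happens strictly inside each outer-training
    partition; outer-test subjects are only ever scored.
    """
    y = table.y
    n = len(table)
    outer = make_cv_scheme(y, config.outer_folds, config.outer_repetitions, config.seed_for("outer"))

    vote_pos = np.zeros(n)
    vote_neg = np.zeros(n)
    score_sum = np.zeros(n)
    ensembles: list[EnsembleModel] = []
    caches: list[_PartitionCache] = []

    for rep in range(config.outer_repetitions):
        for fold in range(config.outer_folds):
            train_idx = outer.train_indices(rep, fold)
            test_idx = outer.test_indices(rep, fold)
            train_tbl = table.subset(train_idx)
            test_tbl = table.subset(test_idx)
            y_train = y[train_idx]

            inner = make_cv_scheme(
                y_train,
                config.inner_folds,
                config.inner_repetitions,
                config.seed_for("inner", rep, fold),
            )
            parts = []
            for irep in range(config.inner_repetitions):
                for ifold in range(config.inner_folds):
                    itr = inner.train_indices(irep, ifold)
                    ite = inner.test_indices(irep, ifold)
                    pm = fit_preprocess(train_tbl.subset(itr), modality, config.k_neighbours)
                    Xtr = apply_preprocess(pm, train_tbl.subset(itr), modality)
                    Xte = apply_preprocess(pm, train_tbl.subset(ite), modality)
                    parts.append((pm, irep, ifold, itr, ite, Xtr, Xte))

            fit_sets = [(Xtr, y_train[itr], Xte, y_train[ite]) for (_, _, _, itr, ite, Xtr, Xte) in parts]
            C = tune_C(fit_sets, config.c_grid)

            base_models: list[BaseModel] = []
            cache = _PartitionCache([], [])
            for (pm, irep, ifold, itr, ite, Xtr, Xte) in parts:
                trace = greedy_forward_select(
                    [(Xtr, y_train[itr], Xte, y_train[ite])],
                    C,
                    max_features=config.max_features,
                )
                mask = trace.final_mask
                model = train_svm(Xtr[:, mask], y_train[itr], C, selected_features=mask)
                base_models.append(
                    BaseModel(pm, model, trace, irep, ifold, train_idx[itr], train_idx[ite])
                )
                Z = apply_preprocess(pm, test_tbl, modality)
                s = decision_values(model, Z[:, mask])
                vote_pos[test_idx] += s > 0
                vote_neg[test_idx] += s <= 0
                score_sum[test_idx] += s
                if keep_cache:
                    cache.inner_train_X.append(Xtr)
                    cache.outer_test_X.append(Z)
            ensembles.append(
                EnsembleModel(
                    modality,
                    rep,
                    fold,
                    train_idx,
                    test_idx,
                    C,
                    base_models,
                    table.feature_names(modality),
                )
            )
            if keep_cache:
                caches.append(cache)

    records = aggregate_records(table.subject_ids, y, vote_pos, vote_neg, score_sum)
    metrics = compute_metrics(
        records["true_label"].to_numpy(),
        records["voted_label"].to_numpy(),
        records["decision_score"].to_numpy(),
    )
    return NestedCVResult(modality, ensembles, records, metrics, outer, caches if keep_cache else None)
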