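"""Inference around trained ensembles: permutation significance,
frozen-model external validation (OOCV), decision-score group
statistics, clinical correlations, and demographic tests.

Permutation testing follows the frozen-subset design: outcome labels
are permuted freely across the cohort, every linear SVM of the nested
CV is retrained on the permuted labels *re-using the feature subsets,
tuned C, fold assignments and preprocessing of the observed-label
run*, and the null distribution collects the permuted out-of-training
balanced accuracies.  The p-value is the fraction of permuted BACs
greater than or equal to the observed one (the conservative
(k+1)/(n+1) variant is reported alongside).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CASE, CONTROL, SubjectTable
from .metrics import MetricsReport, compute_metrics
from .nested_cv import EnsembleModel, NestedCVResult, aggregate_records
from .preprocess import apply_preprocess
from .svm import balanced_accuracy, decision_values, train_svm

__all__ = [
    "PermutationNull",
    "GroupComparison",
    "permutation_test",
    "oocv_apply",
    "compare_decision_scores",
    "correlate_scores",
    "two_sample_t",
    "t_from_summary",
    "chi2_2x2",
    "demographic_tests",
]


class StatsError(ValueError):
    """A statistical comparison is undefined for the given groups."""


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PermutationNull:
    n_permutations: int
    permuted_bacs: np.ndarray
    observed_bac: float
    p_value: float
    p_value_conservative: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _partition_matrices(result: NestedCVResult, table: SubjectTable):
    """Per-partition training/outer-test matrices, from cache or recomputed."""
    for k, ens in enumerate(result.ensembles):
        if result.caches is not None:
            cache = result.caches[k]
            yield ens, cache.inner_train_X, cache.outer_test_X
        else:
            xtr, xte = [], []
            test_tbl = table.subset(ens.outer_test_idx)
            for b in ens.base_models:
                xtr.append(apply_preprocess(b.preprocess, table.subset(b.inner_train_idx), ens.modality))
                xte.append(apply_preprocess(b.preprocess, test_tbl, ens.modality))
            yield ens, xtr, xte


def permutation_test(
    result: NestedCVResult,
    table: SubjectTable,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationNull:
    """Null distribution of out-of-training BAC under label permutation."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = table.y
    n = len(table)
    rng = np.random.default_rng(seed)
    observed = result.metrics.BAC

    partitions = list(_partition_matrices(result, table))
    perm_bacs = np.empty(n_permutations)
    for p in range(n_permutations):
        y_perm = y[rng.permutation(n)]
        vote_pos = np.zeros(n)
        vote_neg = np.zeros(n)
        score_sum = np.zeros(n)
        for ens, xtr_list, xte_list in partitions:
            test_idx = ens.outer_test_idx
            for b, Xtr, Z in zip(ens.base_models, xtr_list, xte_list):
                mask = b.trace.final_mask
                ytr = y_perm[b.inner_train_idx]
                if np.unique(ytr).size < 2:
                    # degenerate permutation: constant vote for the only class
                    s = np.full(len(test_idx), float(ytr[0]))
                else:
                    model = train_svm(Xtr[:, mask], ytr, ens.regularization_C)
                    s = decision_values(model, Z[:, mask])
                vote_pos[test_idx] += s > 0
                vote_neg[test_idx] += s <= 0
                score_sum[test_idx] += s
        rec = aggregate_records(table.subject_ids, y_perm, vote_pos, vote_neg, score_sum)
        perm_bacs[p] = 100.0 * balanced_accuracy(
            rec["true_label"].to_numpy(), rec["voted_label"].to_numpy()
        )
    k = int(np.sum(perm_bacs >= observed))
    return PermutationNull(
        n_permutations,
        perm_bacs,
        observed,
        k / n_permutations,
        (k + 1) / (n_permutations + 1),
        alpha,
    )


# ---------------------------------------------------------------------------
# Out-of-sample cross-validation (frozen-model external application)
# ---------------------------------------------------------------------------


def oocv_apply(
    ensembles: Sequence[EnsembleModel], external: SubjectTable
) -> tuple[pd.DataFrame, MetricsReport | None]:
    """Apply every frozen base model of every partition to an external
    cohort, without any retraining.

    Returns per-subject decision records (majority vote and mean
    geometric score over all base models) and, when the external
    cohort carries case/control labels, a metrics report.  Unlabeled
    staging cohorts yield records only.
    """
    n = len(external)
    vote_pos = np.zeros(n)
    vote_neg = np.zeros(n)
    score_sum = np.zeros(n)
    for ens in ensembles:
        for b in ens.base_models:
            Z = apply_preprocess(b.preprocess, external, ens.modality)
            s = decision_values(b.model, Z[:, b.trace.final_mask])
            vote_pos += s > 0
            vote_neg += s <= 0
            score_sum += s
    y_true = external.y if external.is_labeled else np.zeros(n, dtype=int)
    records = aggregate_records(external.subject_ids, y_true, vote_pos, vote_neg, score_sum)
    if not external.is_labeled:
        records = records.drop(columns=["true_label"])
        return records, None
    metrics = compute_metrics(
        records["true_label"].to_numpy(),
        records["voted_label"].to_numpy(),
        records["decision_score"].to_numpy(),
    )
    return records, metrics


# ---------------------------------------------------------------------------
# Decision-score group statistics (staging, Phase 3)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroupComparison:
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], float]
    group_means: dict[str, float]
    group_ses: dict[str, float]


def compare_decision_scores(
    records_by_group: Mapping[str, np.ndarray], posthoc: str = "tukey"
) -> GroupComparison:
    """One-way ANOVA over decision scores with pairwise post-hoc contrasts.

    ``posthoc`` is "tukey" (Tukey HSD) or "t" (plain pairwise t-tests,
    uncorrected).
    """
    names = list(records_by_group)
    groups = [np.asarray(records_by_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise StatsError(f"group {name!r} has fewer than 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):  # degenerate: no within-group variance anywhere
        F, p = 0.0, 1.0
    F, p = float(F), float(p)
    pairwise: dict[tuple[str, str], float] = {}
    if posthoc == "tukey":
        res = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairwise[(names[i], names[j])] = float(res.pvalue[i, j])
    elif posthoc == "t":
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairwise[(names[i], names[j])] = float(
                    stats.ttest_ind(groups[i], groups[j]).pvalue
                )
    else:
        raise ValueError(f"unknown post-hoc procedure {posthoc!r}")
    means = {n: float(np.mean(g)) for n, g in zip(names, groups)}
    ses = {n: float(np.std(g, ddof=1) / np.sqrt(g.size)) for n, g in zip(names, groups)}
    return GroupComparison(F, p, pairwise, means, ses)


def correlate_scores(scores: np.ndarray, clinical: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with two-sided p.

    Pairs with a missing clinical value are dropped; at least three
    complete pairs are required.
    """
    scores = np.asarray(scores, dtype=float)
    clinical = np.asarray(clinical, dtype=float)
    ok = ~(np.isnan(scores) | np.isnan(clinical))
    if ok.sum() < 3:
        raise StatsError("need at least 3 complete pairs")
    rho, p = stats.spearmanr(scores[ok], clinical[ok])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Demographic tests
# ---------------------------------------------------------------------------


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance t from printed group summaries."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction for 2x2 counts."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise StatsError("expected a 2x2 count table")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    if len(groups) < 2 or any(np.asarray(g).size < 2 for g in groups):
        raise StatsError("ANOVA needs >= 2 groups of >= 2 observations")
    F, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(F), float(p)


def demographic_tests(
    table_a: SubjectTable,
    table_b: SubjectTable,
    continuous: Sequence[str] = ("age",),
) -> pd.DataFrame:
    """Group-difference tests between two cohorts/groups.

    Continuous variables get a pooled two-sample t; the 2x2 gender
    split gets a continuity-corrected chi-square.
    """
    rows = []
    for var in continuous:
        a = table_a.data[var].to_numpy(dtype=float)
        b = table_b.data[var].to_numpy(dtype=float)
        t, p = two_sample_t(a, b)
        rows.append({"variable": var, "test": "t", "statistic": t, "p": p})
    counts = np.array(
        [
            [int((table_a.data["gender"] == 1).sum()), int((table_a.data["gender"] == 0).sum())],
            [int((table_b.data["gender"] == 1).sum()), int((table_b.data["gender"] == 0).sum())],
        ]
    )
    chi2, p = chi2_2x2(counts)
    rows.append({"variable": "gender", "test": "chi2", "statistic": chi2, "p": p})
    return pd.DataFrame(rows)


def split_scores_by_label(records: pd.DataFrame, table: SubjectTable) -> dict[str, np.ndarray]:
    """Decision scores grouped by the table's diagnostic labels."""
    labels = pd.Series(table.labels, index=table.subject_ids)
    out: dict[str, np.ndarray] = {}
    for label in pd.unique(labels):
        ids = labels.index[labels == label]
        sel = records.set_index("subject_id").loc[ids, "decision_score"]
        out[str(label)] = sel.to_numpy(dtype=float)
    return out


#: canonical display names for labels in staging comparisons
LABEL_ORDER = (CONTROL, CASE)
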