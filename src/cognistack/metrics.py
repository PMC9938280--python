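"""Classification performance metrics.

Conventions follow the clinical-classifier literature: sensitivity,
specificity, balanced accuracy (BAC), PPV and NPV are reported as
percentages; the AUC is the rank-based probability that a randomly
chosen case outscores a randomly chosen control (ties count one half);
LR+ = sensitivity / (100 - specificity) on the percentage scale, with
a perfect specificity reported as an infinite likelihood ratio.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "compute_metrics", "rank_auc"]


class MetricsError(ValueError):
    """Metrics are undefined for the given labels."""


@dataclasses.dataclass
class MetricsReport:
    TN: int
    TP: int
    FN: int
    FP: int
    sensitivity: float
    specificity: float
    BAC: float
    AUC: float
    PPV: float
    NPV: float
    positive_likelihood_ratio: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if math.isinf(d["positive_likelihood_ratio"]):
            d["positive_likelihood_ratio"] = "inf"
        return d


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC from decision-score ranks: P(score_case > score_control), ties 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    neg = y_true == -1
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise MetricsError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> MetricsReport:
    """Confusion counts and all derived measures from voted labels.

    ``y_true``/``y_pred`` use the signed convention (+1 case, -1
    control).  When ``scores`` is omitted the AUC is computed from the
    predicted labels themselves (a coarse two-point ROC).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == -1
    if not pos.any() or not neg.any():
        raise MetricsError("both classes must be present in the truth")
    TP = int(np.sum(pos & (y_pred == 1)))
    FN = int(np.sum(pos & (y_pred == -1)))
    TN = int(np.sum(neg & (y_pred == -1)))
    FP = int(np.sum(neg & (y_pred == 1)))
    auc = rank_auc(y_true, scores if scores is not None else y_pred)
    return metrics_from_counts(TN=TN, TP=TP, FN=FN, FP=FP, AUC=auc)


def metrics_from_counts(TN: int, TP: int, FN: int, FP: int, AUC: float = float("nan")) -> MetricsReport:
    """Derive every reported measure from raw confusion counts."""
    if TP + FN == 0 or TN + FP == 0:
        raise MetricsError("confusion table must contain both true classes")
    sens = 100.0 * TP / (TP + FN)
    spec = 100.0 * TN / (TN + FP)
    bac = (sens + spec) / 2.0
    ppv = 100.0 * TP / (TP + FP) if TP + FP else float("nan")
    npv = 100.0 * TN / (TN + FN) if TN + FN else float("nan")
    lr_plus = sens / (100.0 - spec) if spec < 100.0 else float("inf")
    return MetricsReport(TN, TP, FN, FP, sens, spec, bac, AUC, ppv, npv, lr_plus)
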