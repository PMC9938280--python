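"""Stacked (multimodal) fusion of unimodal classifiers.

The stacker never sees raw features: its inputs are the unimodal
classifiers' *out-of-training* decision scores, one meta-feature per
modality, re-cross-validated under the same nested scheme as the
unimodal runs.  Using only out-of-training scores keeps the meta-level
free of leakage from the unimodal training folds.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .data import AGE_COL, COHORT_COL, GENDER_COL, ID_COL, LABEL_COL, SchemaError, SubjectTable
from .evaluate import oocv_apply
from .nested_cv import EnsembleModel, NestedCVResult, run_nested_cv

__all__ = ["build_meta_features", "run_stacking", "oocv_stacked", "META_MODALITY"]

META_MODALITY = "meta"


def build_meta_features(
    table: SubjectTable, records_by_modality: Mapping[str, pd.DataFrame]
) -> SubjectTable:
    """Meta-feature table: one out-of-training decision score per modality.

    ``records_by_modality`` maps modality name to the decision records
    produced by the unimodal nested CV (or OOCV) on the same subjects;
    every modality must cover exactly the table's subjects.
    """
    base = table.data.loc[:, [ID_COL, COHORT_COL, LABEL_COL, AGE_COL, GENDER_COL]].copy()
    cols = []
    for modality in sorted(records_by_modality):
        rec = records_by_modality[modality]
        scores = rec.set_index("subject_id")["decision_score"]
        if set(scores.index) != set(base[ID_COL]):
            raise SchemaError(f"records for {modality!r} do not cover the table's subjects")
        col = f"score_{modality}"
        base[col] = scores.reindex(base[ID_COL]).to_numpy()
        cols.append(col)
    return SubjectTable(base, {META_MODALITY: tuple(cols)})


def run_stacking(meta: SubjectTable, config: PipelineConfig, keep_cache: bool = True) -> NestedCVResult:
    """Nested CV of the meta-level linear SVM on the decision scores."""
    return run_nested_cv(meta, META_MODALITY, config, keep_cache=keep_cache)


def oocv_stacked(
    unimodal_ensembles: Mapping[str, Sequence[EnsembleModel]],
    stack_ensembles: Sequence[EnsembleModel],
    external: SubjectTable,
):
    """Frozen application of a stacked classifier to an external cohort.

    The external meta-features are produced by applying the frozen
    unimodal ensembles first; the frozen stack then scores the
    resulting meta table.  Returns (records, metrics-or-None) as
    :func:`cognistack.evaluate.oocv_apply` does.
    """
    records_by_modality = {
        m: oocv_apply(ens, external)[0] for m, ens in unimodal_ensembles.items()
    }
    meta = build_meta_features(external, records_by_modality)
    return oocv_apply(stack_ensembles, meta)
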