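"""Subject-level data container shared by every pipeline stage.

A :class:`SubjectTable` wraps a tidy pandas DataFrame with one row per
subject: identifier, cohort name, diagnostic label, the mandatory
covariates (age in years, gender as a binary indicator), optional
clinical scores, and one or more blocks ("modalities") of numeric
feature columns.  Feature cells may be missing; labels and the
mandatory covariates never are.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

ID_COL = "subject_id"
COHORT_COL = "cohort"
LABEL_COL = "label"
AGE_COL = "age"
GENDER_COL = "gender"
MANDATORY_COLS = (ID_COL, COHORT_COL, LABEL_COL, AGE_COL, GENDER_COL)

#: optional clinical score columns recognised by the loader
CLINICAL_COLS = ("gaf", "panss_total", "ymrs_total", "med_equivalent_dose")


class SchemaError(ValueError):
    """A table does not satisfy the expected column schema."""


@dataclasses.dataclass
class SubjectTable:
    """Per-subject features, labels and covariates.

    Parameters
    ----------
    data:
        DataFrame holding the mandatory columns, optional clinical
        columns and all feature columns.
    modalities:
        Mapping from modality name to the ordered tuple of feature
        column names belonging to that block.  Blocks must be disjoint
        and jointly account for every feature column.
    """

    data: pd.DataFrame
    modalities: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        seen: set[str] = set()
        for name, cols in self.modalities.items():
            cols = tuple(cols)
            self.modalities[name] = cols
            absent = [c for c in cols if c not in self.data.columns]
            if absent:
                raise SchemaError(f"modality {name!r} references absent columns {absent}")
            overlap = seen.intersection(cols)
            if overlap:
                raise SchemaError(f"modality {name!r} overlaps another block: {sorted(overlap)}")
            seen.update(cols)
        for col in (LABEL_COL, AGE_COL, GENDER_COL):
            if self.data[col].isna().any():
                raise SchemaError(f"column {col!r} contains missing values")
        self.data = self.data.reset_index(drop=True)

    # -- basic census ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data[ID_COL].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.data[LABEL_COL].to_numpy()

    @property
    def is_labeled(self) -> bool:
        """True when every subject carries a case/control label."""
        return bool(np.isin(self.labels, (CONTROL, CASE)).all())

    @property
    def y(self) -> np.ndarray:
        """Signed labels: +1 for cases (patients), -1 for controls."""
        if not self.is_labeled:
            raise SchemaError("table contains unlabeled (staging) subjects")
        return np.where(self.labels == CASE, 1, -1)

    # -- accessors ------------------------------------------------------
    def feature_names(self, modality: str) -> tuple[str, ...]:
        try:
            return self.modalities[modality]
        except KeyError:
            raise SchemaError(f"unknown modality {modality!r}") from None

    def features(self, modality: str) -> np.ndarray:
        """Feature matrix (subjects x features) as float with NaN for missing."""
        return self.data.loc[:, list(self.feature_names(modality))].to_numpy(dtype=float)

    def covariates(self) -> np.ndarray:
        """Design columns [age, gender] used for confound removal."""
        return self.data.loc[:, [AGE_COL, GENDER_COL]].to_numpy(dtype=float)

    def clinical(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise SchemaError(f"clinical column {name!r} not present")
        return self.data[name].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SubjectTable":
        """Row subset (copy); modality structure is preserved."""
        idx = np.asarray(indices)
        return SubjectTable(self.data.iloc[idx].copy(), dict(self.modalities))

    def with_features(self, modality: str, values: np.ndarray) -> "SubjectTable":
        """Copy of the table with one modality's feature block replaced."""
        cols = list(self.feature_names(modality))
        if values.shape != (len(self), len(cols)):
            raise SchemaError(
                f"replacement block has shape {values.shape}, expected {(len(self), len(cols))}"
            )
        out = self.data.copy()
        out.loc[:, cols] = values
        return SubjectTable(out, dict(self.modalities))


def concat_tables(tables: Iterable[SubjectTable]) -> SubjectTable:
    """Stack cohorts that share the same modality structure."""
    tables = list(tables)
    first = tables[0]
    for t in tables[1:]:
        if t.modalities != first.modalities:
            raise SchemaError("cannot concatenate tables with different modality blocks")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return SubjectTable(data, dict(first.modalities))


def infer_modalities(columns: Iterable[str], prefixes: Mapping[str, str]) -> dict[str, tuple[str, ...]]:
    """Group feature columns by modality prefix (e.g. ``cognitive_``)."""
    out: dict[str, tuple[str, ...]] = {}
    for modality, prefix in prefixes.items():
        cols = tuple(c for c in columns if c.startswith(prefix))
        if cols:
            out[modality] = cols
    return out
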