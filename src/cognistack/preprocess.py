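"""Fold-safe preprocessing: scaling, kNN-median imputation, confound removal.

Every parameter is estimated on a training partition only and then
applied, frozen, to any other data.  The chain order is fixed:

1. feature-wise min-max scaling to [0, 1] on observed training values
   (constant features map to 0; test values outside the training range
   are *not* clamped);
2. k-nearest-neighbour imputation of missing cells — each missing
   value is replaced by the median of that feature over the k = 7
   nearest training subjects, with Euclidean distance computed over
   mutually observed scaled coordinates and normalized by the number
   of shared coordinates;
3. residualization of age and gender: per-feature least-squares betas
   on [intercept, age, gender] estimated on the scaled + imputed
   training matrix and subtracted using each subject's own covariates.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import SchemaError, SubjectTable

__all__ = ["PreprocessModel", "fit_preprocess", "apply_preprocess", "knn_impute_value"]

DEFAULT_K_NEIGHBOURS = 7


class FitError(ValueError):
    """Preprocessing cannot be estimated from the given training data."""


class ImputationError(ValueError):
    """No eligible reference rows for a requested imputation."""


@dataclasses.dataclass
class PreprocessModel:
    """Frozen preprocessing parameters for one modality.

    ``reference`` is the scaled training matrix with its original
    missingness pattern preserved: it is the neighbour pool for
    imputation.  ``medians`` are per-feature medians of the observed
    scaled training values (fallback when a query shares no observed
    coordinate with any eligible neighbour).
    """

    feature_names: tuple[str, ...]
    offsets: np.ndarray
    ranges: np.ndarray
    reference: np.ndarray
    medians: np.ndarray
    betas: np.ndarray  # (n_features, 3): intercept, age, gender
    k_neighbours: int = DEFAULT_K_NEIGHBOURS

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "offsets": self.offsets.tolist(),
            "ranges": self.ranges.tolist(),
            "reference": np.where(np.isnan(self.reference), None, self.reference).tolist(),
            "medians": self.medians.tolist(),
            "betas": self.betas.tolist(),
            "k_neighbours": self.k_neighbours,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessModel":
        ref = np.array(
            [[np.nan if v is None else v for v in row] for row in d["reference"]], dtype=float
        )
        return cls(
            feature_names=tuple(d["feature_names"]),
            offsets=np.asarray(d["offsets"], dtype=float),
            ranges=np.asarray(d["ranges"], dtype=float),
            reference=ref,
            medians=np.asarray(d["medians"], dtype=float),
            betas=np.asarray(d["betas"], dtype=float),
            k_neighbours=int(d["k_neighbours"]),
        )


def _scale(x: np.ndarray, offsets: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - offsets) / ranges
    # degenerate (constant) features map to 0 everywhere, keeping the map total
    out[:, ranges == 0] = 0.0
    out[np.isnan(x)] = np.nan
    return out


def _shared_distances(reference: np.ndarray, query_row: np.ndarray) -> np.ndarray:
    """Distance from a query to every reference row over shared coordinates.

    d(q, r) = sqrt( sum_shared (q_j - r_j)^2 / n_shared ); rows sharing
    no observed coordinate get +inf.
    """
    diff = reference - query_row
    shared = ~np.isnan(diff)
    sq = np.where(shared, diff * diff, 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=1) / n_shared)
    d[n_shared == 0] = np.inf
    return d


def knn_impute_value(
    reference: np.ndarray,
    query_row: np.ndarray,
    feature: int,
    k: int,
    median: float | None = None,
) -> float:
    """Impute one cell from the k nearest eligible reference rows.

    Eligible rows observe ``feature``.  Ties in distance are broken by
    lower row index; if the query shares no observed coordinate with
    any eligible row the feature's training median is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = np.flatnonzero(~np.isnan(reference[:, feature]))
    if eligible.size == 0:
        raise ImputationError(f"no reference row observes feature {feature}")
    d = _shared_distances(reference[eligible], query_row)
    finite = np.isfinite(d)
    if not finite.any():
        if median is None:
            median = float(np.nanmedian(reference[:, feature]))
        return float(median)
    elig = eligible[finite]
    d = d[finite]
    order = np.argsort(d, kind="stable")  # stable: equal distances keep index order
    chosen = elig[order[: min(k, elig.size)]]
    return float(np.median(reference[chosen, feature]))


def _impute_matrix(x: np.ndarray, model: PreprocessModel) -> np.ndarray:
    """kNN-impute every missing cell of a scaled matrix against the model."""
    out = x.copy()
    ref = model.reference
    observed_ref = ~np.isnan(ref)
    for i in np.flatnonzero(np.isnan(x).any(axis=1)):
        row = x[i]
        missing = np.flatnonzero(np.isnan(row))
        d_all = _shared_distances(ref, row)
        for j in missing:
            elig = observed_ref[:, j] & np.isfinite(d_all)
            idx = np.flatnonzero(elig)
            if idx.size == 0:
                if not observed_ref[:, j].any():
                    raise ImputationError(
                        f"no training value for feature {model.feature_names[j]!r}"
                    )
                out[i, j] = model.medians[j]
                continue
            order = np.argsort(d_all[idx], kind="stable")
            chosen = idx[order[: min(model.k_neighbours, idx.size)]]
            out[i, j] = np.median(ref[chosen, j])
    return out


def fit_preprocess(
    train: SubjectTable, modality: str, k_neighbours: int = DEFAULT_K_NEIGHBOURS
) -> PreprocessModel:
    """Estimate the full preprocessing chain on one training partition.

    Never reads labels, and never reads any subject outside ``train``.
    """
    if k_neighbours < 1:
        raise ValueError("k_neighbours must be >= 1")
    names = train.feature_names(modality)
    x = train.features(modality)
    all_missing = np.isnan(x).all(axis=0)
    if all_missing.any():
        bad = [names[j] for j in np.flatnonzero(all_missing)]
        raise FitError(f"feature(s) with no observed training value: {bad}")
    offsets = np.nanmin(x, axis=0)
    ranges = np.nanmax(x, axis=0) - offsets
    scaled = _scale(x, offsets, ranges)
    medians = np.nanmedian(scaled, axis=0)
    model = PreprocessModel(
        feature_names=names,
        offsets=offsets,
        ranges=ranges,
        reference=scaled,
        medians=medians,
        betas=np.zeros((len(names), 3)),
        k_neighbours=k_neighbours,
    )
    imputed = _impute_matrix(scaled, model)
    design = np.column_stack([np.ones(len(train)), train.covariates()])
    betas, *_ = np.linalg.lstsq(design, imputed, rcond=None)
    model.betas = betas.T
    return model


def apply_preprocess(model: PreprocessModel, data: SubjectTable, modality: str) -> np.ndarray:
    """Apply a frozen preprocessing model; observed values are never altered
    by imputation, and out-of-range values are not clamped."""
    names = data.feature_names(modality)
    if names != model.feature_names:
        raise SchemaError(
            f"feature columns differ from the fitted model: {names} vs {model.feature_names}"
        )
    x = data.features(modality)
    scaled = _scale(x, model.offsets, model.ranges)
    imputed = _impute_matrix(scaled, model)
    design = np.column_stack([np.ones(len(data)), data.covariates()])
    return imputed - design @ model.betas.T
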