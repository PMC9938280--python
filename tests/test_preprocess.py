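"""Fold-safe preprocessing: scaling, kNN-median imputation, residualization."""

import numpy as np
import pandas as pd
import pytest

from cognistack.data import SubjectTable
from cognistack.preprocess import (
    FitError,
    apply_preprocess,
    fit_preprocess,
    knn_impute_value,
)


def make_table(features, age=None, gender=None, label="control"):
    features = np.asarray(features, dtype=float)
    n = len(features)
    cols = {f"m_{j}": features[:, j] for j in range(features.shape[1])}
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "cohort": "t",
            "label": label,
            "age": age if age is not None else np.linspace(20, 40, n),
            "gender": gender if gender is not None else np.arange(n) % 2,
            **cols,
        }
    )
    return SubjectTable(df, {"m": tuple(cols)})


def brute_force_knn(reference, query, feature, k):
    """Independent oracle: exhaustive distance enumeration."""
    dists = []
    for i, row in enumerate(reference):
        if np.isnan(row[feature]):
            continue
        shared = ~(np.isnan(row) | np.isnan(query))
        if shared.sum() == 0:
            continue
        d = np.sqrt(np.sum((row[shared] - query[shared]) ** 2) / shared.sum())
        dists.append((d, i))
    dists.sort()  # ties resolved by the lower row index
    chosen = [reference[i][feature] for _, i in dists[:k]]
    if not chosen:
        return float(np.nanmedian(reference[:, feature]))
    return float(np.median(chosen))


class TestScaling:
    def test_min_max_maps_to_unit_interval(self):
        table = make_table([[2.0], [4.0], [6.0]])
        model = fit_preprocess(table, "m")
        assert model.offsets[0] == 2.0 and model.ranges[0] == 4.0
        # kill the confound betas to observe the raw scaling
        model.betas[:] = 0.0
        out = apply_preprocess(model, make_table([[4.0], [2.0], [6.0]]), "m")
        assert out[:, 0] == pytest.approx([0.5, 0.0, 1.0])

    def test_out_of_range_values_are_not_clamped(self):
        model = fit_preprocess(make_table([[2.0], [4.0], [6.0]]), "m")
        model.betas[:] = 0.0
        out = apply_preprocess(model, make_table([[8.0], [0.0]]), "m")
        assert out[:, 0] == pytest.approx([1.5, -0.5])

    def test_constant_feature_maps_to_zero(self):
        model = fit_preprocess(make_table([[5.0], [5.0], [5.0]]), "m")
        assert model.ranges[0] == 0.0
        model.betas[:] = 0.0
        out = apply_preprocess(model, make_table([[5.0], [7.0]]), "m")
        assert np.all(out[:, 0] == 0.0)


class TestResidualization:
    def test_perfect_confound_leaves_zero_residuals(self):
        age = np.array([20.0, 25.0, 30.0, 35.0, 40.0, 45.0])
        table = make_table((2 * age)[:, None], age=age, gender=np.zeros(6))
        model = fit_preprocess(table, "m")
        out = apply_preprocess(model, table, "m")
        assert np.all(np.abs(out[:, 0]) < 1e-10)

    def test_training_residuals_are_orthogonal_to_confounds(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 60, 40)
        gender = rng.integers(0, 2, 40)
        x = rng.standard_normal((40, 3)) + 0.5 * age[:, None] / 10 + 0.3 * gender[:, None]
        table = make_table(x, age=age, gender=gender)
        model = fit_preprocess(table, "m")
        out = apply_preprocess(model, table, "m")
        for j in range(3):
            assert abs(np.corrcoef(out[:, j], age)[0, 1]) < 1e-8
            assert abs(np.corrcoef(out[:, j], gender)[0, 1]) < 1e-8


class TestImputation:
    def test_knn_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.standard_normal((20, 5))
        ref[rng.random((20, 5)) < 0.25] = np.nan
        ref[:, 2][np.isnan(ref[:, 2])] = 0.0  # keep the target feature observed somewhere
        for q in range(10):
            query = rng.standard_normal(5)
            query[rng.random(5) < 0.3] = np.nan
            query[2] = np.nan
            for k in (1, 3, 7, 50):
                got = knn_impute_value(ref, query, feature=2, k=k)
                assert got == pytest.approx(brute_force_knn(ref, query, 2, k))

    def test_query_identical_to_reference_row_recovers_it(self):
        ref = np.array([[0.0, 0.0, 5.0], [10.0, 10.0, 9.0], [20.0, 20.0, 1.0]])
        query = np.array([10.0, 10.0, np.nan])
        assert knn_impute_value(ref, query, feature=2, k=1) == 9.0

    def test_k_larger_than_pool_uses_all_eligible_rows(self):
        ref = np.array([[0.0, 1.0], [1.0, 3.0], [2.0, 5.0]])
        query = np.array([0.5, np.nan])
        assert knn_impute_value(ref, query, feature=1, k=100) == 3.0

    def test_observed_values_are_never_altered(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((15, 4))
        x[3, 1] = np.nan
        table = make_table(x)
        model = fit_preprocess(table, "m")
        model.betas[:] = 0.0
        out = apply_preprocess(model, table, "m")
        scaled = (x - model.offsets) / model.ranges
        observed = ~np.isnan(x)
        assert np.allclose(out[observed], scaled[observed])
        assert np.isfinite(out).all()

    def test_disconnected_query_falls_back_to_training_median(self):
        ref = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        query = np.array([np.nan, np.nan])
        got = knn_impute_value(ref, query, feature=1, k=3)
        assert got == 4.0


class TestContracts:
    def test_apply_is_deterministic_and_idempotent_on_training_data(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((25, 4))
        x[rng.random((25, 4)) < 0.1] = np.nan
        table = make_table(x)
        model = fit_preprocess(table, "m")
        a = apply_preprocess(model, table, "m")
        b = apply_preprocess(model, table, "m")
        assert np.array_equal(a, b)

    def test_fit_is_invariant_to_non_training_subjects(self):
        """Leakage guard: changing data outside the training partition
        cannot change anything the model learned."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 4))
        table = make_table(x)
        train_idx = np.arange(0, 20)
        model_a = fit_preprocess(table.subset(train_idx), "m")
        x2 = x.copy()
        x2[20:] = 1e6 * rng.standard_normal((10, 4))
        model_b = fit_preprocess(make_table(x2).subset(train_idx), "m")
        assert np.array_equal(model_a.offsets, model_b.offsets)
        assert np.array_equal(model_a.betas, model_b.betas)

    def test_feature_with_no_observed_training_value_raises(self):
        x = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(FitError, match="m_1"):
            fit_preprocess(make_table(x), "m")

    def test_roundtrip_serialization(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 3))
        x[2, 1] = np.nan
        table = make_table(x)
        model = fit_preprocess(table, "m")
        from cognistack.preprocess import PreprocessModel

        clone = PreprocessModel.from_dict(model.to_dict())
        assert np.array_equal(
            apply_preprocess(model, table, "m"), apply_preprocess(clone, table, "m")
        )
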