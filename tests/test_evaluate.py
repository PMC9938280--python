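"""Metrics engine, permutation inference, OOCV, and group statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cognistack.evaluate import (
    StatsError,
    chi2_2x2,
    compare_decision_scores,
    correlate_scores,
    oocv_apply,
    permutation_test,
    t_from_summary,
    two_sample_t,
)
from cognistack.metrics import MetricsError, compute_metrics, metrics_from_counts, rank_auc


class TestMetrics:
    def test_published_style_confusion_table(self):
        """A cognitive classifier confusion table (84/42/17/11) yields the
        familiar derived metrics."""
        m = metrics_from_counts(TN=84, TP=42, FN=17, FP=11)
        assert m.sensitivity == pytest.approx(71.2, abs=0.05)
        assert m.specificity == pytest.approx(88.4, abs=0.05)
        assert m.BAC == pytest.approx(79.8, abs=0.05)
        assert m.PPV == pytest.approx(79.2, abs=0.05)
        assert m.NPV == pytest.approx(83.2, abs=0.05)
        assert m.positive_likelihood_ratio == pytest.approx(6.1, abs=0.05)

    def test_metric_identities_hold(self):
        m = metrics_from_counts(TN=85, TP=35, FN=24, FP=10)
        assert m.BAC == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)
        assert m.positive_likelihood_ratio == pytest.approx(
            m.sensitivity / (100 - m.specificity), abs=1e-12
        )
        assert m.TP + m.FN == 59 and m.TN + m.FP == 95

    def test_perfect_predictions(self):
        y = np.r_[np.ones(10, dtype=int), -np.ones(10, dtype=int)]
        m = compute_metrics(y, y, y.astype(float))
        assert m.BAC == 100.0
        assert np.isinf(m.positive_likelihood_ratio)

    def test_single_class_truth_raises(self):
        with pytest.raises(MetricsError):
            compute_metrics(np.ones(5, dtype=int), np.ones(5, dtype=int))


class TestAUC:
    def test_random_scores_give_half(self):
        rng = np.random.default_rng(0)
        y = np.where(rng.random(10_000) < 0.4, 1, -1)
        auc = rank_auc(y, rng.standard_normal(10_000))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_exhaustive_pair_count_oracle(self):
        rng = np.random.default_rng(1)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        y[:2] = [1, -1]
        scores = np.round(rng.standard_normal(40), 1)  # rounding forces ties
        wins = half = total = 0
        for i, j in itertools.product(np.flatnonzero(y == 1), np.flatnonzero(y == -1)):
            total += 1
            if scores[i] > scores[j]:
                wins += 1
            elif scores[i] == scores[j]:
                half += 1
        assert rank_auc(y, scores) == pytest.approx((wins + 0.5 * half) / total)


class TestPermutation:
    def test_strong_signal_yields_small_p(self, nested_result, small_table):
        null = permutation_test(nested_result, small_table, n_permutations=30, seed=5)
        assert null.observed_bac > 70
        assert null.p_value <= 0.1
        assert null.p_value_conservative == pytest.approx(
            (np.sum(null.permuted_bacs >= null.observed_bac) + 1) / 31
        )

    def test_p_value_estimator_edges(self, nested_result, small_table):
        null = permutation_test(nested_result, small_table, n_permutations=10, seed=6)
        k = int(np.sum(null.permuted_bacs >= null.observed_bac))
        assert null.p_value == k / 10
        assert 0.0 <= null.p_value <= 1.0

    def test_preprocessing_is_reused_not_refitted(self, nested_result, small_table):
        """Cached and recomputed permutation paths agree exactly."""
        import dataclasses

        no_cache = dataclasses.replace(nested_result, caches=None)
        a = permutation_test(nested_result, small_table, n_permutations=5, seed=7)
        b = permutation_test(no_cache, small_table, n_permutations=5, seed=7)
        assert np.array_equal(a.permuted_bacs, b.permuted_bacs)


class TestOOCV:
    def test_labeled_external_cohort_gets_metrics(self, nested_result, small_table):
        records, metrics = oocv_apply(nested_result.ensembles, small_table)
        assert metrics is not None and 0 <= metrics.BAC <= 100
        assert len(records) == len(small_table)

    def test_unlabeled_cohort_gets_records_only(self, nested_result):
        from cognistack.simulate import generate_cohort, staging_cohort_spec

        spec = staging_cohort_spec(
            "CHR", 35, effect_fraction=0.5,
            n_features={"cognitive": 8, "sociocognitive": 6}, seed=8,
        )
        table, _ = generate_cohort(spec)
        records, metrics = oocv_apply(nested_result.ensembles, table)
        assert metrics is None
        assert len(records) == 35 and "true_label" not in records.columns

    def test_application_is_deterministic_and_frozen(self, nested_result, small_table):
        import json

        from cognistack.nested_cv import EnsembleModel

        before = json.dumps([e.to_dict() for e in nested_result.ensembles], sort_keys=True)
        rec1, _ = oocv_apply(nested_result.ensembles, small_table)
        rec2, _ = oocv_apply(nested_result.ensembles, small_table)
        after = json.dumps([e.to_dict() for e in nested_result.ensembles], sort_keys=True)
        assert rec1.equals(rec2)
        assert before == after  # artifacts untouched by application
        clone = [EnsembleModel.from_dict(d) for d in json.loads(before)]
        rec3, _ = oocv_apply(clone, small_table)
        assert np.array_equal(rec1["decision_score"], rec3["decision_score"])


class TestGroupComparison:
    def test_identical_groups_have_zero_f(self):
        g = np.arange(10.0)
        cmp = compare_decision_scores({"a": g, "b": g.copy(), "c": g.copy()})
        assert cmp.anova_F == pytest.approx(0.0)
        assert cmp.anova_p == pytest.approx(1.0)

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(25), rng.standard_normal(30) + 0.4
        cmp = compare_decision_scores({"a": a, "b": b}, posthoc="t")
        t, _ = two_sample_t(a, b)
        assert cmp.anova_F == pytest.approx(t**2, rel=1e-10)

    def test_separated_group_is_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "hc": rng.standard_normal(30),
            "chr": rng.standard_normal(30),
            "pat": rng.standard_normal(30) + 2.0,
        }
        cmp = compare_decision_scores(groups)
        assert cmp.anova_p < 0.001
        assert cmp.pairwise[("hc", "pat")] < 0.01
        assert cmp.pairwise[("hc", "chr")] > 0.05

    def test_tiny_group_raises(self):
        with pytest.raises(StatsError):
            compare_decision_scores({"a": np.arange(5.0), "b": np.array([1.0])})


class TestSpearman:
    def test_monotone_pairings(self):
        x = np.arange(10.0)
        assert correlate_scores(x, x**3)[0] == pytest.approx(1.0)
        assert correlate_scores(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.standard_normal(10), 1)
        z = np.round(rng.standard_normal(10), 1)
        rho, _ = correlate_scores(x, z)
        # oracle: Pearson correlation of mid-ranks
        rx, rz = stats.rankdata(x), stats.rankdata(z)
        expected = np.corrcoef(rx, rz)[0, 1]
        assert rho == pytest.approx(expected)

    def test_too_few_pairs_raise(self):
        with pytest.raises(StatsError):
            correlate_scores(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestDemographics:
    def test_pooled_t_reproduces_published_iq_contrast(self):
        """Current IQ 110.13 +/- 11.54 (n=95) vs 89.32 +/- 13.25 (n=59)."""
        t, p = t_from_summary(110.13, 11.54, 95, 89.32, 13.25, 59)
        assert t == pytest.approx(10.3, abs=0.05)
        assert p < 0.001

    def test_yates_chi2_reproduces_published_gender_contrast(self):
        chi2, p = chi2_2x2([[88, 107], [89, 29]])
        assert chi2 == pytest.approx(26.24, abs=0.005)
        assert p < 0.001
        chi2b, pb = chi2_2x2([[36, 59], [30, 29]])
        assert chi2b == pytest.approx(1.99, abs=0.005)
        assert pb > 0.1

    def test_identical_groups_have_zero_t(self):
        g = np.arange(12.0)
        t, p = two_sample_t(g, g.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_table_level_report_covers_age_and_gender(self, small_table):
        from cognistack.evaluate import demographic_tests

        controls = small_table.subset(np.flatnonzero(small_table.labels == "control"))
        cases = small_table.subset(np.flatnonzero(small_table.labels == "case"))
        report = demographic_tests(controls, cases)
        assert set(report["variable"]) == {"age", "gender"}
        # ages were drawn from different group distributions, so t is nonzero
        t_age = float(report.loc[report["variable"] == "age", "statistic"].iloc[0])
        assert t_age != 0.0
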