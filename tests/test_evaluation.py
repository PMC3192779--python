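"""Confusion matrices, diagnostic metrics, Fisher exact test, CIs, t-tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import receptorsig as rs
from receptorsig.cluster import PredictionResult
from receptorsig.data import DataError

from conftest import make_clinical


def make_pred(calls, samples=None):
    samples = samples or [f"s{i}" for i in range(len(calls))]
    return PredictionResult(
        sample_ids=tuple(samples),
        predicted=tuple(calls),
        cluster_centroids=np.zeros((2, 1)),
        orientation_scores=(0.0, 1.0),
    )


class TestConfusion:
    def test_perfect_predictions(self):
        truth = ["positive"] * 6 + ["negative"] * 4
        cm = rs.confusion(make_pred(truth), make_clinical(truth))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (6, 4, 0, 0)

    def test_all_predicted_positive(self):
        truth = ["positive"] * 4 + ["negative"] * 4
        cm = rs.confusion(make_pred(["positive"] * 8), make_clinical(truth))
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (4, 4, 0, 0)

    def test_swapping_pred_and_truth_transposes(self):
        calls = ["positive", "negative", "positive", "negative", "positive"]
        truth = ["positive", "positive", "negative", "negative", "negative"]
        cm1 = rs.confusion(make_pred(calls), make_clinical(truth))
        cm2 = rs.confusion(make_pred(truth), make_clinical(calls))
        assert (cm1.fp, cm1.fn) == (cm2.fn, cm2.fp)
        assert (cm1.tp, cm1.tn) == (cm2.tp, cm2.tn)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(DataError, match="differ"):
            rs.confusion(
                make_pred(["positive"], samples=["a"]),
                make_clinical(["positive"], samples=["b"]),
            )


class TestMetrics:
    def test_perfect_is_100_everywhere(self):
        report = rs.metrics(rs.ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(report, name) == 100.0

    def test_zero_denominator_flags_only_that_metric(self):
        report = rs.metrics(rs.ConfusionMatrix(tp=0, fp=0, tn=8, fn=2))
        assert math.isnan(report.ppv)
        assert report.specificity == 100.0
        assert report.sensitivity == 0.0

    @pytest.mark.parametrize("n", [1, 3, 10, 57])
    def test_metrics_of_perfect_confusion_any_n(self, n):
        report = rs.metrics(rs.ConfusionMatrix(tp=n, fp=0, tn=n, fn=0))
        assert report.accuracy == 100.0 and report.fisher_p <= 1.0


def fisher_enumeration_oracle(tp, fp, fn, tn):
    """Two-sided Fisher by full enumeration of tables with fixed margins."""
    row1, col1, total = tp + fp, tp + fn, tp + fp + fn + tn

    def prob(a):
        return (
            math.comb(col1, a)
            * math.comb(total - col1, row1 - a)
            / math.comb(total, row1)
        )

    lo, hi = max(0, row1 - (total - col1)), min(row1, col1)
    p_obs = prob(tp)
    return sum(prob(a) for a in range(lo, hi + 1) if prob(a) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_two_by_two_diagonal_example(self):
        assert rs.fisher_exact_two_sided(
            rs.ConfusionMatrix(tp=2, fp=0, tn=2, fn=0)
        ) == pytest.approx(1 / 3, abs=1e-12)

    def test_uniform_table_gives_p_one(self):
        assert rs.fisher_exact_two_sided(
            rs.ConfusionMatrix(tp=10, fp=10, tn=10, fn=10)
        ) == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 16, 4))
            if tp + fp + fn + tn == 0:
                continue
            cm = rs.ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
            assert rs.fisher_exact_two_sided(cm) == pytest.approx(
                fisher_enumeration_oracle(tp, fp, fn, tn), abs=1e-10
            )

    def test_symmetric_under_transpose_and_double_swap(self):
        cm = rs.ConfusionMatrix(tp=9, fp=3, tn=14, fn=5)
        p = rs.fisher_exact_two_sided(cm)
        transposed = rs.ConfusionMatrix(tp=9, fp=5, tn=14, fn=3)
        swapped = rs.ConfusionMatrix(tp=14, fp=5, tn=9, fn=3)
        assert rs.fisher_exact_two_sided(transposed) == pytest.approx(p, abs=1e-12)
        assert rs.fisher_exact_two_sided(swapped) == pytest.approx(p, abs=1e-12)


class TestCI:
    def test_closed_form_oracle_three_values(self):
        # t(0.975, df=2) = 4.302653: interval = mean -/+ t * sd / sqrt(3)
        values = [77.78, 59.09, 76.27]
        est = rs.ci_mean_t(values)
        mean, sd = np.mean(values), np.std(values, ddof=1)
        t = stats.t.ppf(0.975, 2)
        assert est.lower == pytest.approx(mean - t * sd / math.sqrt(3), abs=1e-10)
        assert est.upper == pytest.approx(mean + t * sd / math.sqrt(3), abs=1e-10)

    def test_upper_bound_may_exceed_100(self):
        est = rs.ci_mean_t([94.94, 94.26, 99.54])
        assert est.upper > 100.0

    def test_constant_values_zero_width(self):
        est = rs.ci_mean_t([80.0, 80.0, 80.0])
        assert est.lower == est.upper == est.mean == 80.0

    def test_single_value_rejected(self):
        with pytest.raises(DataError):
            rs.ci_mean_t([50.0])

    def test_approaches_normal_limit_as_n_grows(self):
        rng = np.random.default_rng(2)
        values = 70 + rng.normal(0, 5, 400)
        est = rs.ci_mean_t(values)
        z = stats.norm.ppf(0.975)
        sd = values.std(ddof=1)
        normal_half = z * sd / math.sqrt(len(values))
        assert (est.upper - est.lower) / 2 == pytest.approx(normal_half, rel=0.01)


class TestMethodComparison:
    def test_identical_vectors_paired_is_degenerate(self):
        with pytest.raises(DataError, match="zero variance"):
            rs.compare_methods_ttest([80, 85, 90], [80, 85, 90], paired=True)

    def test_near_constant_shift_is_significant_and_matches_oracle(self):
        a = np.array([70.0, 75.0, 80.0, 85.0, 90.0])
        b = a + 10 + np.array([0.01, -0.02, 0.015, -0.01, 0.005])
        p = rs.compare_methods_ttest(a, b, paired=True)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert p < 0.05

    def test_unpaired_larger_than_paired_for_correlated_vectors(self):
        rng = np.random.default_rng(4)
        a = 70 + rng.normal(0, 8, 6)
        b = a + 3 + rng.normal(0, 0.5, 6)
        assert rs.compare_methods_ttest(a, b, paired=False) > rs.compare_methods_ttest(
            a, b, paired=True
        )


class TestReportSerialization:
    def test_json_and_text_roundtrip_core_fields(self):
        import json

        report = rs.metrics(rs.ConfusionMatrix(tp=183, fp=9, tn=68, fn=26))
        data = json.loads(report.to_json())
        assert data["confusion"] == {"tp": 183, "fp": 9, "tn": 68, "fn": 26}
        assert data["accuracy"] == 87.76
        text = report.to_text()
        assert "sensitivity\t87.56" in text and "npv\t72.34" in text
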