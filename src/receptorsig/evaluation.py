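"""Diagnostic-test evaluation of predicted vs clinical receptor status.

Conventions: "positive" means clinically receptor-positive; sensitivity is
the fraction of clinical positives called positive, specificity the fraction
of clinical negatives called negative, PPV/NPV the precision of the positive
and negative calls. Association is tested with the two-sided Fisher exact
test (minimum-likelihood summation, the R ``fisher.test`` convention).
Cross-dataset uncertainty is a t-based confidence interval over per-dataset
metric values, deliberately not clamped to [0, 100].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .cluster import PredictionResult
from .data import ClinicalTable, DataError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "IntervalEstimate",
    "confusion",
    "metrics",
    "fisher_exact_two_sided",
    "ci_mean_t",
    "compare_methods_ttest",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of predicted vs clinical status."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.total < 1:
            raise DataError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_table(self) -> np.ndarray:
        """[[tp, fp], [fn, tn]] — predictor rows, clinical columns."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else float("nan")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix plus the five headline percentages and Fisher p.

    A metric whose denominator is zero is NaN-flagged, never fabricated.
    """

    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fisher_p: float

    def to_dict(self) -> dict:
        d = {
            "confusion": asdict(self.confusion),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "fisher_p": self.fisher_p,
        }
        return d

    def to_json(self) -> str:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        d = self.to_dict()
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            d[k] = clean(round(d[k], 2)) if d[k] == d[k] else None
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        cm = self.confusion
        lines = [
            f"tp\t{cm.tp}",
            f"fp\t{cm.fp}",
            f"tn\t{cm.tn}",
            f"fn\t{cm.fn}",
        ]
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            lines.append(f"{name}\t{'NA' if value != value else f'{value:.2f}'}")
        lines.append(f"fisher_p\t{self.fisher_p:.6g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IntervalEstimate:
    """t-based confidence interval for a metric across datasets (percent)."""

    mean: float
    lower: float
    upper: float
    level: float
    n_datasets: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise DataError("interval must bracket the mean")


def confusion(pred: PredictionResult, clin: ClinicalTable) -> ConfusionMatrix:
    """Cross-tabulate predictions against clinical truth (same sample sets)."""
    if set(pred.sample_ids) != set(clin.sample_ids):
        raise DataError("prediction and clinical sample sets differ")
    truth = clin.status
    tp = fp = tn = fn = 0
    for sample, call in zip(pred.sample_ids, pred.predicted):
        actual = truth[sample]
        if actual == "unknown":
            raise DataError(f"sample {sample!r} has unknown clinical status")
        if call == "positive":
            if actual == "positive":
                tp += 1
            else:
                fp += 1
        else:
            if actual == "negative":
                tn += 1
            else:
                fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Accuracy, sensitivity, specificity, PPV, NPV (percent) and Fisher p."""
    return EvaluationReport(
        confusion=cm,
        accuracy=_pct(cm.tp + cm.tn, cm.total),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
        fisher_p=fisher_exact_two_sided(cm),
    )


def fisher_exact_two_sided(cm: ConfusionMatrix) -> float:
    """Two-sided Fisher exact p for the 2x2 table.

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one.
    """
    return float(stats.fisher_exact(cm.as_table(), alternative="two-sided").pvalue)


def ci_mean_t(metric_values: Sequence[float], level: float = 0.95) -> IntervalEstimate:
    """mean +/- t_{1-(1-level)/2, n-1} * sd / sqrt(n) over per-dataset values.

    Not clamped: with few datasets the upper bound can exceed 100%.
    """
    values = np.asarray(list(metric_values), dtype=float)
    if len(values) < 2:
        raise DataError("confidence interval requires at least 2 values")
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    tcrit = float(stats.t.ppf(1 - (1 - level) / 2, df=n - 1))
    half = tcrit * sd / math.sqrt(n)
    return IntervalEstimate(mean=mean, lower=mean - half, upper=mean + half,
                            level=level, n_datasets=n)


def compare_methods_ttest(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = True
) -> float:
    """Two-sided t-test p comparing a metric between two methods.

    Paired by dataset by default (the same datasets evaluated under both
    methods). Zero variance of the paired differences is degenerate and
    raises rather than returning a fabricated p.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if paired:
        if len(a) != len(b):
            raise DataError("paired comparison requires equal-length vectors")
        if len(a) < 2:
            raise DataError("at least 2 paired values required")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise DataError("zero variance of paired differences; t-test undefined")
        return float(stats.ttest_rel(a, b).pvalue)
    if len(a) < 2 or len(b) < 2:
        raise DataError("at least 2 values per group required")
    return float(stats.ttest_ind(a, b).pvalue)
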