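"""Model/Results interface tying the pipeline stages together.

:class:`SignatureDiscovery` is built from a training expression matrix and
clinical table (optionally a second training pair, used when the first
cannot discriminate between cutoffs); :meth:`SignatureDiscovery.fit` runs
the correlation ranking, the cutoff sweep with 2-means status calling, and
the sensitivity+specificity maximization, returning a
:class:`SignatureDiscoveryResults` holding the signature, the sweep table
and the training evaluation. The results object predicts and evaluates on
validation datasets, clustering each dataset independently — only the
signature transfers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import correlation as corr_mod
from .cluster import PredictionResult, predict_status, predict_with_best_probe_em
from .correlation import (
    CorrelationTable,
    SweepPoint,
    best_probe,
    choose_optimal,
    select_signature,
    spearman_vs_status,
    sweep,
)
from .data import ClinicalTable, DataError, ExpressionMatrix, Signature, align
from .evaluation import (
    EvaluationReport,
    IntervalEstimate,
    ci_mean_t,
    compare_methods_ttest,
    confusion,
    metrics,
)

__all__ = ["SignatureDiscovery", "SignatureDiscoveryResults", "default_grid"]


def default_grid(start: float = 0.30, stop: float = 0.60, step: float = 0.01) -> np.ndarray:
    """Cutoff grid at 0.01 granularity spanning the working range of rho
    cutoffs for receptor signatures."""
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


class SignatureDiscovery:
    """Derive a receptor signature from one (or two) training datasets."""

    def __init__(
        self,
        expr: ExpressionMatrix,
        clinical: ClinicalTable,
        secondary_expr: ExpressionMatrix | None = None,
        secondary_clinical: ClinicalTable | None = None,
    ):
        if (secondary_expr is None) != (secondary_clinical is None):
            raise DataError("secondary training set requires both matrix and clinical table")
        self.expr, self.clinical = align(expr, clinical)
        self.receptor = clinical.receptor
        self.secondary: tuple[ExpressionMatrix, ClinicalTable] | None = None
        if secondary_expr is not None:
            if secondary_clinical.receptor != self.receptor:
                raise DataError("secondary training set targets a different receptor")
            self.secondary = align(secondary_expr, secondary_clinical)

    @classmethod
    def from_files(
        cls,
        expr_path: str,
        clinical_path: str,
        secondary_expr_path: str | None = None,
        secondary_clinical_path: str | None = None,
    ) -> "SignatureDiscovery":
        from .io import read_clinical_table, read_expression_matrix

        expr = read_expression_matrix(expr_path)
        clin = read_clinical_table(clinical_path)
        sec_expr = sec_clin = None
        if secondary_expr_path is not None:
            sec_expr = read_expression_matrix(secondary_expr_path)
            sec_clin = read_clinical_table(secondary_clinical_path)
        return cls(expr, clin, sec_expr, sec_clin)

    def fit(
        self,
        cutoff_grid: Sequence[float] | None = None,
        seed: int = 0,
        flat_tolerance: float = corr_mod.FLAT_SWEEP_TOLERANCE,
    ) -> "SignatureDiscoveryResults":
        grid = list(cutoff_grid) if cutoff_grid is not None else list(default_grid())

        def predictor(e: ExpressionMatrix, s: Signature) -> np.ndarray:
            return predict_status(e, s, seed=seed).binary()

        labels = self.clinical.binary_labels().to_numpy()
        corr = spearman_vs_status(self.expr, labels)
        sweep_primary = sweep(self.expr, labels, grid, predictor, self.receptor)

        sweep_secondary = None
        used_secondary = False
        sums = [p.sum_sens_spec for p in sweep_primary if p.valid]
        if sums and (max(sums) - min(sums) < flat_tolerance):
            if self.secondary is None:
                # surfaces the two-training-set requirement
                choose_optimal(sweep_primary, None, flat_tolerance)
            sec_expr, sec_clin = self.secondary
            sec_labels = sec_clin.binary_labels().to_numpy()
            sweep_secondary = sweep(sec_expr, sec_labels, grid, predictor, self.receptor)
            used_secondary = True

        cutoff = choose_optimal(sweep_primary, sweep_secondary, flat_tolerance)
        signature = select_signature(
            corr, cutoff, self.receptor, source_tag=f"derived(seed={seed})"
        )
        train_pred = predict_status(self.expr, signature, seed=seed)
        train_report = metrics(confusion(train_pred, self.clinical))

        return SignatureDiscoveryResults(
            model=self,
            signature=signature,
            cutoff=cutoff,
            correlation=corr,
            sweep_primary=tuple(sweep_primary),
            sweep_secondary=tuple(sweep_secondary) if sweep_secondary else None,
            used_secondary=used_secondary,
            training_report=train_report,
            seed=seed,
            grid=tuple(grid),
        )


@dataclass(frozen=True)
class SignatureDiscoveryResults:
    """Fitted signature plus everything needed to audit and reuse it."""

    model: SignatureDiscovery
    signature: Signature
    cutoff: float
    correlation: CorrelationTable
    sweep_primary: tuple[SweepPoint, ...]
    sweep_secondary: tuple[SweepPoint, ...] | None
    used_secondary: bool
    training_report: EvaluationReport
    seed: int
    grid: tuple[float, ...]

    @property
    def best_probe_id(self) -> str:
        """Probe with the highest signed rho in the training correlation."""
        return best_probe(self.correlation)

    def sweep_table(self) -> pd.DataFrame:
        rows = []
        for label, points in (
            ("primary", self.sweep_primary),
            ("secondary", self.sweep_secondary or ()),
        ):
            for p in points:
                rows.append(
                    {
                        "training_set": label,
                        "cutoff": p.cutoff,
                        "n_probes": p.n_probes,
                        "sensitivity": p.sensitivity,
                        "specificity": p.specificity,
                        "sum_sens_spec": p.sum_sens_spec,
                    }
                )
        return pd.DataFrame(rows)

    def predict(self, expr: ExpressionMatrix, seed: int | None = None) -> PredictionResult:
        """Call statuses on a new dataset (clustered independently)."""
        return predict_status(expr, self.signature, seed=self.seed if seed is None else seed)

    def predict_baseline(
        self, expr: ExpressionMatrix, probe_id: str | None = None, seed: int | None = None
    ) -> PredictionResult:
        """Single-probe EM baseline call; defaults to the best training probe."""
        probe = probe_id if probe_id is not None else self.best_probe_id
        return predict_with_best_probe_em(
            expr, probe, seed=self.seed if seed is None else seed
        )

    def evaluate(
        self, expr: ExpressionMatrix, clinical: ClinicalTable, seed: int | None = None
    ) -> EvaluationReport:
        expr_a, clin_a = align(expr, clinical)
        pred = self.predict(expr_a, seed=seed)
        return metrics(confusion(pred, clin_a))

    def evaluate_many(
        self,
        datasets: Sequence[tuple[str, ExpressionMatrix, ClinicalTable]],
        level: float = 0.95,
        seed: int | None = None,
    ) -> tuple[dict[str, EvaluationReport], pd.DataFrame]:
        """Per-dataset reports plus a cross-dataset t-interval summary."""
        reports = {
            name: self.evaluate(expr, clin, seed=seed) for name, expr, clin in datasets
        }
        rows = []
        for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            values = [getattr(r, metric) for r in reports.values()]
            finite = [v for v in values if v == v]
            if len(finite) >= 2:
                est: IntervalEstimate = ci_mean_t(finite, level)
                rows.append(
                    {
                        "metric": metric,
                        "mean": est.mean,
                        "lower": est.lower,
                        "upper": est.upper,
                        "level": level,
                        "n_datasets": est.n_datasets,
                    }
                )
        return reports, pd.DataFrame(rows)

    def compare_with_baseline(
        self,
        datasets: Sequence[tuple[str, ExpressionMatrix, ClinicalTable]],
        metric: str = "specificity",
        probe_id: str | None = None,
        paired: bool = True,
        seed: int | None = None,
    ) -> float:
        """Paired (by dataset) t-test p: signature vs single-probe baseline."""
        sig_vals, base_vals = [], []
        for _, expr, clin in datasets:
            expr_a, clin_a = align(expr, clin)
            sig_vals.append(getattr(metrics(confusion(self.predict(expr_a, seed=seed), clin_a)), metric))
            base_pred = self.predict_baseline(expr_a, probe_id=probe_id, seed=seed)
            base_vals.append(getattr(metrics(confusion(base_pred, clin_a)), metric))
        return compare_methods_ttest(sig_vals, base_vals, paired=paired)

    def save_signature(self, path: str) -> None:
        from .io import write_signature

        write_signature(self.signature, path)

    def summary(self) -> str:
        tr = self.training_report
        lines = [
            f"Receptor signature discovery ({self.signature.receptor})",
            "=" * 56,
            f"training samples        {self.model.expr.n_samples}",
            f"probes ranked           {len(self.correlation.entries)}"
            + (
                f"  (+{len(self.correlation.excluded_probes)} constant, excluded)"
                if self.correlation.excluded_probes
                else ""
            ),
            f"cutoff grid             {self.grid[0]:.2f} .. {self.grid[-1]:.2f}"
            f"  ({len(self.grid)} points)",
            f"selected cutoff         {self.cutoff:.2f}"
            + ("  (secondary training set used: primary sweep flat)" if self.used_secondary else ""),
            f"signature size          {len(self.signature)} probe sets",
            f"best probe (signed rho) {self.best_probe_id}"
            f"  rho={self.correlation.entries[self.best_probe_id]:.2f}",
            "-" * 56,
            "training performance (vs clinical status):",
            f"  accuracy    {tr.accuracy:6.2f} %",
            f"  sensitivity {tr.sensitivity:6.2f} %",
            f"  specificity {tr.specificity:6.2f} %",
            f"  PPV         {tr.ppv:6.2f} %",
            f"  NPV         {tr.npv:6.2f} %",
            f"  Fisher p    {tr.fisher_p:.3g}",
        ]
        return "\n".join(lines)
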