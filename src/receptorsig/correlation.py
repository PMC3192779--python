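"""Spearman-correlation feature ranking and cutoff-sweep signature selection.

Every probe set is ranked by the Spearman correlation (Pearson correlation of
mid-ranks, average ranks for ties) between its expression vector and the 0/1
receptor status. Candidate signatures are the probes with ``|rho| >= cutoff``
over a grid of cutoffs; each candidate is scored by clustering the training
samples into two groups and comparing the calls with the clinical labels, and
the cutoff maximizing sensitivity + specificity wins. Selection is nested:
raising the cutoff can only shrink the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .data import ClinicalTable, DataError, ExpressionMatrix, Signature

__all__ = [
    "CorrelationTable",
    "SweepPoint",
    "spearman_vs_status",
    "select_signature",
    "sweep",
    "choose_optimal",
    "best_probe",
    "FLAT_SWEEP_TOLERANCE",
]

#: sum(sens, spec) range (percentage points) below which a sweep counts as flat
FLAT_SWEEP_TOLERANCE = 0.5


@dataclass(frozen=True)
class CorrelationTable:
    """Per-probe Spearman rho against binary status.

    ``entries`` maps probe ID -> rho; probes whose expression has zero rank
    variance (constant probes, for which the correlation is undefined) are
    listed in ``excluded_probes`` instead.
    """

    entries: dict[str, float]
    n_samples: int
    excluded_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for probe, rho in self.entries.items():
            if not np.isfinite(rho) or abs(rho) > 1 + 1e-12:
                raise DataError(f"rho out of range for probe {probe!r}: {rho}")
        overlap = set(self.entries) & set(self.excluded_probes)
        if overlap:
            raise DataError(f"probes both scored and excluded: {sorted(overlap)}")


@dataclass(frozen=True)
class SweepPoint:
    """One cutoff's operating point on the training data.

    Metrics are percentages; ``sensitivity``/``specificity`` are NaN when the
    cutoff retains no probes (``n_probes == 0``) and the point is kept in the
    sweep rather than dropped.
    """

    cutoff: float
    n_probes: int
    sensitivity: float
    specificity: float

    @property
    def sum_sens_spec(self) -> float:
        return self.sensitivity + self.specificity

    @property
    def valid(self) -> bool:
        return self.n_probes > 0 and np.isfinite(self.sum_sens_spec)


def _binary_labels(labels: "np.ndarray | Sequence[int] | ClinicalTable") -> np.ndarray:
    if isinstance(labels, ClinicalTable):
        labels = labels.binary_labels().to_numpy()
    arr = np.asarray(labels, dtype=float)
    if arr.ndim != 1:
        raise DataError("labels must be one-dimensional")
    if not set(np.unique(arr)) <= {0.0, 1.0}:
        raise DataError("labels must be binary 0/1")
    return arr


def spearman_vs_status(
    expr: ExpressionMatrix, labels: "np.ndarray | Sequence[int] | ClinicalTable"
) -> CorrelationTable:
    """Spearman rho of every probe against the 0/1 status vector.

    Computed as the Pearson correlation of mid-ranks, vectorized across the
    probe dimension. Requires both classes present and at least 3 samples.
    """
    y = _binary_labels(labels)
    if expr.n_samples != len(y):
        raise DataError(
            f"matrix has {expr.n_samples} samples but {len(y)} labels given"
        )
    if len(y) < 3:
        raise DataError("at least 3 samples required")
    if y.min() == y.max():
        raise DataError("both status classes must be present")

    x = expr.values  # (n_probes, n_samples)
    rx = rankdata(x, axis=1)
    ry = rankdata(y)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    sx = np.sqrt((rx_c**2).sum(axis=1))
    sy = np.sqrt((ry_c**2).sum())
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / (sx * sy)
    rho = np.clip(rho, -1.0, 1.0)

    probes = expr.probe_ids
    entries = {p: float(r) for p, r, c in zip(probes, rho, constant) if not c}
    excluded = tuple(p for p, c in zip(probes, constant) if c)
    return CorrelationTable(entries, n_samples=len(y), excluded_probes=excluded)


def select_signature(
    corr: CorrelationTable, cutoff: float, receptor: str, source_tag: str = ""
) -> Signature:
    """Retain exactly the probes with ``|rho| >= cutoff`` (signed rho kept).

    Selection on the absolute coefficient admits anti-correlated probes,
    matching signatures that carry negative blocks. Raises when the cutoff
    retains nothing.
    """
    if not (0.0 < cutoff < 1.0):
        raise DataError(f"cutoff must lie in (0, 1), got {cutoff}")
    pairs = [(p, r) for p, r in corr.entries.items() if abs(r) >= cutoff]
    if not pairs:
        raise DataError(f"no probes reach |rho| >= {cutoff}")
    return Signature.from_pairs(receptor, cutoff, pairs, source_tag)


def sweep(
    expr: ExpressionMatrix,
    labels: "np.ndarray | Sequence[int] | ClinicalTable",
    cutoff_grid: Sequence[float],
    predictor: Callable[[ExpressionMatrix, Signature], np.ndarray],
    receptor: str = "ER",
) -> list[SweepPoint]:
    """Score each cutoff by predicting training statuses with ``predictor``.

    ``predictor(expr, signature)`` must return a 0/1 call per sample (the
    2-means cluster predictor in the standard pipeline). Cutoffs retaining no
    probes yield a SweepPoint with ``n_probes=0`` and NaN metrics.
    """
    grid = list(cutoff_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise DataError("cutoff grid must be strictly increasing")
    y = _binary_labels(labels)
    corr = spearman_vs_status(expr, y)
    points: list[SweepPoint] = []
    for cutoff in grid:
        try:
            sig = select_signature(corr, cutoff, receptor)
        except DataError:
            points.append(SweepPoint(cutoff, 0, float("nan"), float("nan")))
            continue
        calls = np.asarray(predictor(expr, sig), dtype=int)
        tp = int(np.sum((calls == 1) & (y == 1)))
        fn = int(np.sum((calls == 0) & (y == 1)))
        tn = int(np.sum((calls == 0) & (y == 0)))
        fp = int(np.sum((calls == 1) & (y == 0)))
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        points.append(SweepPoint(cutoff, len(sig), sens, spec))
    return points


def choose_optimal(
    sweeps_primary: Sequence[SweepPoint],
    sweeps_secondary: Sequence[SweepPoint] | None = None,
    flat_tolerance: float = FLAT_SWEEP_TOLERANCE,
) -> float:
    """Cutoff maximizing sensitivity + specificity; two-training-set fallback.

    When the primary sweep is flat (range of the summed metric below
    ``flat_tolerance`` percentage points — a training set that cannot
    discriminate between cutoffs) the secondary sweep decides; lacking one, an
    error instructs the caller to supply a second training set. Ties break
    toward the larger cutoff, i.e. the smaller signature.
    """
    primary = [p for p in sweeps_primary if p.valid]
    if not primary:
        raise DataError("primary sweep has no valid points")
    sums = np.array([p.sum_sens_spec for p in primary])
    if sums.max() - sums.min() < flat_tolerance:
        if sweeps_secondary is None:
            raise DataError(
                "primary sweep is flat (sum of sensitivity and specificity "
                "constant across the grid); a second training set is required"
            )
        secondary = [p for p in sweeps_secondary if p.valid]
        if not secondary:
            raise DataError("secondary sweep has no valid points")
        primary, sums = secondary, np.array([p.sum_sens_spec for p in secondary])
    best = sums.max()
    candidates = [p.cutoff for p, s in zip(primary, sums) if s == best]
    return max(candidates)


def best_probe(corr: CorrelationTable) -> str:
    """Probe with the maximal signed rho; lexicographic tie-break."""
    if not corr.entries:
        raise DataError("correlation table is empty")
    best_rho = max(corr.entries.values())
    return min(p for p, r in corr.entries.items() if r == best_rho)
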