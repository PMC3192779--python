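"""Core domain objects: expression matrices, clinical status tables, signatures.

The pipeline operates on bulk microarray-style expression matrices (probe sets
in rows, samples in columns, log-scale normalized intensities) together with
per-sample clinical receptor status (ER, PR or ERBB2; positive / negative /
unknown, as established by protein- or DNA-level assays such as IHC or FISH).
A :class:`Signature` is the derived object: a set of probe sets retained at a
Spearman-correlation cutoff, each with its signed correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "Signature",
    "SignatureEntry",
    "RECEPTORS",
    "STATUS_VALUES",
    "align",
    "deduplicate_against",
]

RECEPTORS = ("ER", "PR", "ERBB2")
STATUS_VALUES = ("positive", "negative", "unknown")


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe-by-sample matrix of log-scale normalized expression intensities.

    Parameters
    ----------
    frame
        DataFrame with probe IDs as the index and sample IDs as columns.
        Every entry must be finite; duplicate probe or sample IDs are
        rejected.
    platform_tag
        Free-text platform annotation (e.g. ``"HG-U133A"``).
    """

    frame: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        idx = self.frame.index
        cols = self.frame.columns
        if len(idx) == 0:
            raise DataError("expression matrix has no probes")
        if len(cols) == 0:
            raise DataError("expression matrix has no samples")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate probe ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(f"duplicate sample ID: {dup!r}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        """(n_probes, n_samples) float array."""
        return self.frame.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.frame.columns]
        if missing:
            raise DataError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)], self.platform_tag)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.frame.index]
        if missing:
            raise DataError(f"probes not in matrix: {missing}")
        return ExpressionMatrix(self.frame.loc[list(probe_ids), :], self.platform_tag)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.platform_tag == other.platform_tag
            and self.frame.index.equals(other.frame.index)
            and self.frame.columns.equals(other.frame.columns)
            and np.array_equal(self.frame.to_numpy(), other.frame.to_numpy())
        )


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical receptor status.

    ``status`` maps sample ID -> one of ``positive``/``negative``/``unknown``.
    Unknown is encoded explicitly (rather than by absence) so that per-dataset
    sample bookkeeping is reproducible.
    """

    status: pd.Series  # index: sample IDs, values in STATUS_VALUES
    receptor: str
    assay: str = ""

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise DataError(f"receptor must be one of {RECEPTORS}, got {self.receptor!r}")
        if self.status.index.has_duplicates:
            dup = self.status.index[self.status.index.duplicated()][0]
            raise DataError(f"duplicate sample ID: {dup!r}")
        bad = set(self.status) - set(STATUS_VALUES)
        if bad:
            raise DataError(f"invalid status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.index)

    def known(self) -> "ClinicalTable":
        """Restrict to samples with determinate (non-unknown) status."""
        return ClinicalTable(self.status[self.status != "unknown"], self.receptor, self.assay)

    def binary_labels(self) -> pd.Series:
        """0/1 labels (negative=0, positive=1); raises if any unknown remains."""
        if (self.status == "unknown").any():
            raise DataError("binary labels requested but unknown statuses present")
        return (self.status == "positive").astype(int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.status.index]
        if missing:
            raise DataError(f"samples not in clinical table: {missing}")
        return ClinicalTable(self.status.loc[list(sample_ids)], self.receptor, self.assay)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicalTable):
            return NotImplemented
        return (
            self.receptor == other.receptor
            and self.assay == other.assay
            and self.status.equals(other.status)
        )


@dataclass(frozen=True)
class SignatureEntry:
    probe_id: str
    rho: float


@dataclass(frozen=True)
class Signature:
    """A receptor signature: probes retained at a correlation cutoff.

    Invariants: ``0 < cutoff < 1``, probe IDs unique, and ``|rho| >= cutoff``
    for every entry. Negative coefficients are legitimate — the ERBB2 and PR
    signatures contain anti-correlated probes.
    """

    receptor: str
    cutoff: float
    entries: tuple[SignatureEntry, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise DataError(f"receptor must be one of {RECEPTORS}, got {self.receptor!r}")
        if not (0.0 < self.cutoff < 1.0):
            raise DataError(f"cutoff must lie in (0, 1), got {self.cutoff}")
        if len(self.entries) == 0:
            raise DataError("signature has no entries")
        ids = [e.probe_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate probe IDs in signature")
        for e in self.entries:
            if not np.isfinite(e.rho) or abs(e.rho) > 1:
                raise DataError(f"rho out of [-1, 1] for probe {e.probe_id!r}")
            if abs(e.rho) < self.cutoff:
                raise DataError(
                    f"|rho|={abs(e.rho):.4f} below cutoff {self.cutoff} "
                    f"for probe {e.probe_id!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return [e.probe_id for e in self.entries]

    @property
    def rhos(self) -> np.ndarray:
        return np.array([e.rho for e in self.entries], dtype=float)

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.rhos)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(
        cls,
        receptor: str,
        cutoff: float,
        pairs: Iterable[tuple[str, float]],
        source_tag: str = "",
    ) -> "Signature":
        return cls(
            receptor,
            cutoff,
            tuple(SignatureEntry(str(p), float(r)) for p, r in pairs),
            source_tag,
        )


def align(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to shared samples with determinate status.

    Sample order follows the expression matrix (deterministic). Raises if the
    intersection is empty or only one status class survives — downstream
    correlation and clustering require both classes.
    """
    known = clin.known()
    shared = [s for s in expr.sample_ids if s in set(known.sample_ids)]
    if not shared:
        raise DataError("no shared samples with known status")
    expr_a = expr.subset_samples(shared)
    clin_a = known.subset(shared)
    present = set(clin_a.status)
    for cls_name in ("positive", "negative"):
        if cls_name not in present:
            raise DataError(f"no {cls_name} samples after alignment")
    return expr_a, clin_a


def deduplicate_against(
    primary_ids: Iterable[str], secondary: ExpressionMatrix
) -> ExpressionMatrix:
    """Drop from ``secondary`` every sample whose ID occurs in ``primary_ids``.

    Mirrors cross-dataset duplicate removal when the same tumors were
    deposited in two accessions; the duplicate ID list is caller-supplied.
    """
    primary = set(primary_ids)
    keep = [s for s in secondary.sample_ids if s not in primary]
    if not keep:
        raise DataError("deduplication removed every sample")
    if len(keep) == secondary.n_samples:
        return secondary
    return secondary.subset_samples(keep)
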