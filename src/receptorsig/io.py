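"""Readers and writers for the package's tab-delimited interchange formats.

Expression matrix: TSV, first column ``probe_id``, remaining columns sample
IDs, one row per probe (the shape of a GEO series-matrix export after
normalization). Clinical table: TSV with columns ``sample_id``, ``status``,
``receptor``, ``assay``. Signature: TSV with a ``#``-prefixed header block
(receptor, cutoff, source) followed by ``probe_id``/``rho`` columns.
All round-trip exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ClinicalTable,
    DataError,
    ExpressionMatrix,
    Signature,
    STATUS_VALUES,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_signature",
    "write_signature",
]


def read_expression_matrix(path: str | Path, platform_tag: str = "") -> ExpressionMatrix:
    """Load a probes-in-rows TSV, validating IDs and cells.

    Raises :class:`DataError` naming the offending probe for duplicate IDs,
    and the (probe, sample) coordinates for missing or non-numeric cells.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise DataError(f"{path}: expected a header row with sample IDs")
    header = rows[0]
    sample_ids = header[1:]
    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    seen: set[str] = set()
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise DataError(f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}")
        probe = row[0]
        if probe in seen:
            raise DataError(f"{path}: duplicate probe ID {probe!r}")
        seen.add(probe)
        probe_ids.append(probe)
        for j, cell in enumerate(row[1:]):
            try:
                value = float(cell)
            except ValueError:
                value = np.nan
            if not np.isfinite(value):
                raise DataError(
                    f"{path}: missing or non-numeric value at probe {probe!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            data[i, j] = value
    frame = pd.DataFrame(data, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(frame, platform_tag)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.frame.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status", "receptor"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: clinical table requires columns {sorted(required)}")
    bad = set(df["status"]) - set(STATUS_VALUES)
    if bad:
        raise DataError(f"{path}: invalid status values {sorted(bad)}")
    receptors = df["receptor"].unique()
    if len(receptors) != 1:
        raise DataError(f"{path}: clinical table mixes receptors {list(receptors)}")
    assay = ""
    if "assay" in df.columns:
        assays = df["assay"].fillna("").unique()
        assay = assays[0] if len(assays) == 1 else ";".join(sorted(assays))
    status = pd.Series(df["status"].values, index=df["sample_id"].values)
    return ClinicalTable(status, receptors[0], assay)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": clin.sample_ids,
            "status": clin.status.values,
            "receptor": clin.receptor,
            "assay": clin.assay,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    meta: dict[str, str] = {}
    pairs: list[tuple[str, float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body or body[0].split("\t")[:2] != ["probe_id", "rho"]:
        raise DataError(f"{path}: expected 'probe_id<TAB>rho' column header")
    for line in body[1:]:
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}: malformed signature row {line!r}")
        pairs.append((fields[0], float(fields[1])))
    if "receptor" not in meta or "cutoff" not in meta:
        raise DataError(f"{path}: signature header must declare receptor and cutoff")
    return Signature.from_pairs(
        meta["receptor"], float(meta["cutoff"]), pairs, meta.get("source", "")
    )


def write_signature(sig: Signature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# receptor = {sig.receptor}\n")
        fh.write(f"# cutoff = {sig.cutoff:.10g}\n")
        fh.write(f"# source = {sig.source_tag}\n")
        fh.write("probe_id\trho\n")
        for entry in sig.entries:
            fh.write(f"{entry.probe_id}\t{entry.rho:.10g}\n")
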