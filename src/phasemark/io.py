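"""Readers and writers for expression matrices, annotations and gene lists.

Supported inputs are delimited matrix files (TSV/CSV with one header row of
ids and one id column) and the table section of a GEO series-matrix file
(the lines between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``).  Outputs are plain TSV plus JSON manifests.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import PHASES, ExpressionMatrix, PhaseTensor, ProbeAnnotation

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _parse_cell(token: str) -> float:
    tok = token.strip().strip('"')
    if tok.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(tok)
    except ValueError:
        return np.nan


def read_expression_matrix(
    path: str | Path, orientation: str = "samples"
) -> ExpressionMatrix:
    """Read a delimited matrix file into samples x probes orientation.

    Parameters
    ----------
    orientation
        ``"samples"`` if file rows are samples, ``"probes"`` if file rows
        are probes (the result is transposed into samples x probes).

    Empty or non-numeric cells are flagged missing.  Duplicate ids and
    ragged rows are hard errors.
    """
    if orientation not in ("samples", "probes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header line and at least one data row")
    delim = _sniff_delimiter(lines[0])
    header = next(csv.reader([lines[0]], delimiter=delim))
    col_ids = [c.strip().strip('"') for c in header[1:]]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = next(csv.reader([ln], delimiter=delim))
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {len(header)})"
            )
        row_ids.append(fields[0].strip().strip('"'))
        rows.append([_parse_cell(tok) for tok in fields[1:]])
    values = np.asarray(rows, dtype=float)
    if orientation == "probes":
        values = values.T
        sample_ids, probe_ids = col_ids, row_ids
    else:
        sample_ids, probe_ids = row_ids, col_ids
    return ExpressionMatrix(sample_ids, probe_ids, values, np.isnan(values))


def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the table section of a GEO series-matrix file.

    Only the lines between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` are consumed; the table has probes in rows
    (ID_REF column) and samples in columns, and is transposed into the
    samples x probes orientation.
    """
    path = Path(path)
    inside = False
    table_lines: list[str] = []
    for ln in path.read_text().splitlines():
        low = ln.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            inside = True
            continue
        if low.startswith("!series_matrix_table_end"):
            inside = False
            continue
        if inside and ln.strip():
            table_lines.append(ln)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table section found")
    # The table is tab-delimited with quoted ids.
    reader = csv.reader(_io.StringIO("\n".join(table_lines)), delimiter="\t")
    header = next(reader)
    sample_ids = [c.strip().strip('"') for c in header[1:]]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, fields in enumerate(reader, start=2):
        if len(fields) != len(header):
            raise ValueError(f"{path}: ragged table row {lineno}")
        probe_ids.append(fields[0].strip().strip('"'))
        rows.append([_parse_cell(tok) for tok in fields[1:]])
    values = np.asarray(rows, dtype=float).T
    return ExpressionMatrix(sample_ids, probe_ids, values, np.isnan(values))


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    """Write a TSV (samples in rows); missing cells are left empty.

    Values are written with full repr precision so that a write/read
    round-trip is bit-identical.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.probe_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "" if matrix.missing_mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_probes)
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


@dataclass
class TensorAssemblyReport:
    """Ids dropped while intersecting the per-phase matrices."""

    dropped_samples: dict[str, list[str]] = field(default_factory=dict)
    dropped_probes: dict[str, list[str]] = field(default_factory=dict)


def assemble_phase_tensor(
    per_phase: dict[str, ExpressionMatrix],
) -> tuple[PhaseTensor, TensorAssemblyReport]:
    """Assemble three phase-labelled matrices into a PhaseTensor.

    The phase matrices are intersected on sample and probe ids (one label
    per patient per phase is required downstream), reordered to the order
    of the Acute matrix, and stored in fixed phase order A, SA, C whatever
    the input order.  A report lists the ids dropped by the intersection.
    """
    if set(per_phase) != set(PHASES):
        raise ValueError(f"phase labels must be exactly {set(PHASES)}, got {set(per_phase)}")
    common_samples = [
        s
        for s in per_phase["A"].sample_ids
        if all(s in per_phase[ph].sample_ids for ph in PHASES)
    ]
    common_probes_set = set(per_phase["A"].probe_ids)
    for ph in PHASES[1:]:
        common_probes_set &= set(per_phase[ph].probe_ids)
    common_probes = [p for p in per_phase["A"].probe_ids if p in common_probes_set]
    if not common_samples:
        raise ValueError("empty sample intersection across phases")
    if not common_probes:
        raise ValueError("empty probe intersection across phases")
    report = TensorAssemblyReport()
    for ph in PHASES:
        m = per_phase[ph]
        ds = [s for s in m.sample_ids if s not in common_samples]
        dp = [p for p in m.probe_ids if p not in common_probes_set]
        if ds:
            report.dropped_samples[ph] = ds
        if dp:
            report.dropped_probes[ph] = dp
    mats = tuple(
        per_phase[ph].subset_samples(common_samples).subset_probes(common_probes)
        for ph in PHASES
    )
    return PhaseTensor(mats), report  # type: ignore[arg-type]


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column delimited file probe_id <tab> gene_id.

    Duplicate identical rows are deduplicated silently; a probe mapped to
    two different genes is a hard error.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        delim = "\t" if "\t" in ln else ","
        fields = [f.strip().strip('"') for f in ln.split(delim)]
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}: malformed annotation row at line {lineno}")
        probe, gene = fields
        if probe in mapping and mapping[probe] != gene:
            raise ValueError(
                f"{path}: probe {probe!r} maps to both "
                f"{mapping[probe]!r} and {gene!r}"
            )
        mapping[probe] = gene
    return ProbeAnnotation(mapping)


def read_gene_list(path: str | Path) -> list[str]:
    """One id per line; '#' starts a comment; order preserved, dupes dropped."""
    out: list[str] = []
    for ln in Path(path).read_text().splitlines():
        name = ln.split("#", 1)[0].strip()
        if name and name not in out:
            out.append(name)
    return out
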