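"""Readers and writers for the TSV dialects and GEO series-matrix text.

Canonical formats:

* expression TSV -- genes in rows (first column ``gene_id``), samples in
  columns; a sidecar two-column TSV (``sample``, ``group``) carries group
  labels;
* probe TSV -- columns ``probe_id, gene_id, gc_fraction, melting_temp,
  position_index`` followed by one intensity column per sample
  (``position_index`` is a 0-based offset along the transcript);
* GEO series-matrix -- ``!``-prefixed metadata lines with the expression
  table between ``!series_matrix_table_begin`` and
  ``!series_matrix_table_end`` (read-only; metadata preserved).

All writers round-trip losslessly with their readers on the packaged
fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortTruth
from .types import ExpressionMatrix, PROBE_META_COLUMNS, ProbeTable


# -- expression matrices -----------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path, groups_path=None) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if groups_path is not None:
        if expr.groups is None:
            raise ValueError("matrix has no group labels to write")
        expr.groups.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")


def read_expression_tsv(path, groups_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=df.index.rename("gene_id"), columns=df.columns,
                          dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise ValueError(
                f"non-numeric cell at gene {row!r}, sample {col!r} in {path}")
        values[col] = converted
    groups = None
    if groups_path is not None:
        g = pd.read_csv(groups_path, sep="\t", index_col=0)
        groups = g["group"]
    return ExpressionMatrix(values=values, groups=groups)


# -- probe tables ------------------------------------------------------------

def write_probe_tsv(probes: ProbeTable, path) -> None:
    probes.data.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path) -> ProbeTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe TSV {path} missing column(s): {missing}")
    return ProbeTable(df)


# -- GEO series matrix -------------------------------------------------------

def read_series_matrix(path) -> tuple[ExpressionMatrix, list[str]]:
    """Parse a GEO series-matrix text file.

    Returns the expression matrix (no group labels; sample ids from the
    table header, quotes stripped) and the list of ``!`` metadata lines as a
    provenance record.  Missing table delimiters are an error.
    """
    metadata: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                saw_begin, in_table = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                saw_end, in_table = True, False
                continue
            if line.startswith("!"):
                metadata.append(line)
            elif in_table and line.strip():
                table_lines.append(line)
    if not (saw_begin and saw_end):
        raise ValueError(f"{path}: series-matrix table delimiters not found")

    def unquote(tok: str) -> str:
        tok = tok.strip()
        if len(tok) >= 2 and tok[0] == tok[-1] == '"':
            tok = tok[1:-1]
        return tok

    header = [unquote(t) for t in table_lines[0].split("\t")]
    rows = []
    index = []
    for line in table_lines[1:]:
        toks = [unquote(t) for t in line.split("\t")]
        index.append(toks[0])
        rows.append([float(t) for t in toks[1:]])
    values = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                          columns=header[1:], dtype=float)
    return ExpressionMatrix(values=values, groups=None), metadata


# -- truth / config ----------------------------------------------------------

def write_truth(truth: CohortTruth, path) -> None:
    path = Path(path)
    payload = truth.to_dict()
    if path.suffix in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_truth(path) -> CohortTruth:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    return CohortTruth.from_dict(payload)
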