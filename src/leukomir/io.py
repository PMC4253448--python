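"""Readers and writers for the tabular formats the pipeline consumes.

Everything is plain TSV (UTF-8, "." decimal separator) except pathway gene
sets, which use GMT semantics (name, description, tab-separated members).
Readers validate and reject malformed input rather than silently coercing.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    ExpressionMatrix,
    IntegrityError,
    ProbeTable,
    SampleSheet,
)

#: default column names for probe-level exports; override via ``dialect`` to
#: accept vendor headers (e.g. a "gTotalProbeSignal"-named signal column).
DEFAULT_PROBE_DIALECT = {
    "probe_id": "probe_id",
    "mirna_id": "mirna_id",
    "sample_id": "sample_id",
    "signal": "signal",
}


def read_probe_table(path: str | Path, dialect: dict[str, str] | None = None) -> ProbeTable:
    """Read a long-format probe signal table.

    ``dialect`` maps canonical field names (probe_id, mirna_id, sample_id,
    signal, optionally detected) to the column headers used in the file.
    Rows whose signal does not parse as a number are rejected with an error.
    """
    mapping = dict(DEFAULT_PROBE_DIALECT)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise ConfigError(f"probe table {path} missing column(s) {missing}; "
                          f"present: {list(df.columns)}")
    rename = {v: k for k, v in mapping.items()}
    df = df.rename(columns=rename)[list(mapping)]
    signals = pd.to_numeric(df["signal"], errors="coerce")
    bad = df.index[signals.isna()]
    if len(bad):
        raise IntegrityError(
            f"{len(bad)} row(s) with unparseable signal, first at line {bad[0] + 2}")
    df["signal"] = signals.astype(float)
    if "detected" in df.columns:
        df["detected"] = df["detected"].astype(str).str.lower().isin(("1", "true", "t", "yes"))
    return ProbeTable(df)


def read_expression_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a miRNA x sample TSV: header row of sample ids, first column of
    miRNA ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise IntegrityError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(values, scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets in GMT layout: name, description, members...

    Gene symbols are upper-cased; empty pathways are rejected.
    """
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntegrityError(f"{path}:{lineno}: GMT line needs name, "
                                     "description and >=1 member")
            name = parts[0]
            members = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not members:
                raise IntegrityError(f"{path}:{lineno}: pathway {name!r} has no members")
            if name in pathways:
                raise IntegrityError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = members
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in pathways.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Read a miRNA -> target-gene mapping.

    Layout: two tab-separated columns, miRNA id and ";"-separated gene symbols.
    miRNA ids are kept verbatim (star forms are distinct entities); gene
    symbols are upper-cased.
    """
    targets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise IntegrityError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mirna, genes = parts
            gene_set = {g.strip().upper() for g in genes.split(";") if g.strip()}
            if not gene_set:
                raise IntegrityError(f"{path}:{lineno}: empty gene set for {mirna!r}")
            targets.setdefault(mirna, set()).update(gene_set)
    return targets


def write_target_map(targets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(targets):
            fh.write(f"{mirna}\t{';'.join(sorted(targets[mirna]))}\n")
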