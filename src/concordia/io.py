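"""Readers and writers for the pipeline's external formats.

Formats
-------
Expression TSV
    ``feature_id<TAB>[length_bp<TAB>]sample1<TAB>sample2 ...`` with one header
    row. ``NA`` marks a non-detected cell and is legal only for proteins.
    Gzipped files (``.gz``) are read transparently.
Design TSV
    ``sample_id<TAB>group`` with a header; group is case/control (PD/HC
    spellings accepted).
GMT
    Standard gene-set dialect: name, description, then tab-separated member
    ids. The description is stored as the set category when it names one
    (``cellular_component``, ``biological_process``, ``functional_group``),
    otherwise the set is filed under ``functional_group``.
JSON run summary
    Schema tag ``concordia_summary_v1``; records thresholds, seeds and counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CATEGORIES,
    PROTEIN,
    TRANSCRIPT,
    CohortDesign,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

SUMMARY_SCHEMA = "concordia_summary_v1"
LENGTH_COLUMN = "length_bp"
_FLOAT_FORMAT = "%.10g"


def read_expression_matrix(path: str | Path, ome: str) -> ExpressionMatrix:
    """Read a feature x sample expression TSV (optionally gzipped).

    A second column named ``length_bp`` is interpreted as per-feature
    transcript length and stripped from the value matrix.
    """
    # pandas silently renames duplicate header fields, so check them raw
    header = pd.read_csv(path, sep="\t", header=None, nrows=1).iloc[0]
    dup = header[1:][header[1:].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    lengths = None
    if LENGTH_COLUMN in df.columns:
        if list(df.columns).index(LENGTH_COLUMN) != 0:
            raise ValueError(f"{LENGTH_COLUMN!r} must be the first data column")
        lengths = df[LENGTH_COLUMN]
        df = df.drop(columns=[LENGTH_COLUMN])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r}: {bad.iloc[0]!r}")
    if ome == TRANSCRIPT and df.isna().any().any():
        raise ValueError("'NA' is not permitted in a transcript count matrix")
    return ExpressionMatrix(ome=ome, values=df, feature_length_bp=lengths)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    if matrix.ome == TRANSCRIPT:
        df = df.astype(int)
    if matrix.feature_length_bp is not None:
        df.insert(0, LENGTH_COLUMN, matrix.feature_length_bp.astype(int))
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FORMAT)


def read_design(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("design table needs columns sample_id and group")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in design: {dup}")
    return CohortDesign(dict(zip(df[sample_col], df[group_col])))


def write_design(design: CohortDesign, path: str | Path) -> None:
    rows = [{"sample_id": s, "group": g} for s, g in design.assignments.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set has an empty member list")
            name, description = parts[0], parts[1]
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(
                    f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            category = description if description in CATEGORIES else "functional_group"
            sets.append(GeneSet(name=name, category=category,
                                members=frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.category, *sorted(s.members)]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a deterministic TSV (fixed float format, no platform newlines)."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA",
              float_format=_FLOAT_FORMAT, lineterminator="\n")


def write_results_tables(results: dict[str, pd.DataFrame], out_dir: str | Path,
                         summary: dict | None = None) -> list[Path]:
    """Write one TSV per named result table plus an optional JSON summary.

    ``results`` maps a base name (e.g. ``"de_protein"``) to a DataFrame. The
    output is deterministic: identical input produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        path = out_dir / f"{name}.tsv"
        write_table(df, path, index=False)
        written.append(path)
    if summary is not None:
        path = out_dir / "summary.json"
        write_summary_json(summary, path)
        written.append(path)
    return written


def write_summary_json(summary: dict, path: str | Path) -> None:
    payload = {"schema": SUMMARY_SCHEMA, **summary}
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
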