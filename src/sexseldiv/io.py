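"""Readers and writers for all tabular formats consumed by the pipeline.

Conventions: assay and double-mating tables are comma-separated with a
header; expression matrices, sample sheets and homology hits are
tab-separated; gene sets are one identifier per line. Row numbers in error
messages are 1-based data rows (the header is row 0).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import check_regime, check_sex
from .expdiv import ExpressionData

logger = logging.getLogger("sexseldiv")

ASSAY_COLUMNS = [
    "individual_id",
    "sex",
    "line_id",
    "regime",
    "mating_population_id",
    "matings",
    "offspring",
]

DOUBLE_MATING_COLUMNS = [
    "female_id",
    "regime",
    "female_line",
    "male_line",
    "eggs_total",
    "hatched",
    "first_mating_ok",
    "second_mating_ok",
]

BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """A row violates a value constraint; the message cites the row."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")
    extras = [c for c in df.columns if c not in required]
    if extras:
        logger.warning("%s: ignoring unrecognized column(s) %s", what, extras)


def _check_nonneg_int(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() | (values != values.round()) | (values < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"{what}: column {col!r} must be a non-negative integer; "
            f"offending value {df[col].iloc[row - 1]!r} on row {row}"
        )
    return values.astype(int)


def read_individual_assays(path: str | Path, dialect: str = ",") -> pd.DataFrame:
    """Read a mating-assay table: one row per individual.

    Returns a DataFrame with columns ``individual_id, sex, line_id, regime,
    mating_population_id, matings, offspring``; unrecognized columns are
    dropped with a logged warning.
    """
    df = pd.read_csv(path, sep=dialect, dtype=str)
    _require_columns(df, ASSAY_COLUMNS, f"assay table {path}")
    df = df[ASSAY_COLUMNS].copy()
    check_sex(df["sex"])
    check_regime(df["regime"])
    df["matings"] = _check_nonneg_int(df, "matings", f"assay table {path}")
    df["offspring"] = _check_nonneg_int(df, "offspring", f"assay table {path}")
    zero_mated = (df["matings"] == 0) & (df["offspring"] > 0)
    if zero_mated.any():
        row = int(np.flatnonzero(zero_mated.to_numpy())[0]) + 1
        raise ValidationError(
            f"assay table {path}: row {row} has offspring > 0 with zero matings"
        )
    return df


def read_double_matings(path: str | Path, dialect: str = ",") -> pd.DataFrame:
    """Read a double-mating table: one row per female.

    ``first_mating_ok``/``second_mating_ok`` accept true/false, 1/0, yes/no.
    """
    df = pd.read_csv(path, sep=dialect, dtype=str)
    _require_columns(df, DOUBLE_MATING_COLUMNS, f"double-mating table {path}")
    df = df[DOUBLE_MATING_COLUMNS].copy()
    check_regime(df["regime"])
    df["eggs_total"] = _check_nonneg_int(df, "eggs_total", f"double-mating table {path}")
    df["hatched"] = _check_nonneg_int(df, "hatched", f"double-mating table {path}")
    over = df["hatched"] > df["eggs_total"]
    if over.any():
        row = int(np.flatnonzero(over.to_numpy())[0]) + 1
        raise ValidationError(
            f"double-mating table {path}: hatched > eggs_total on row {row}"
        )
    for col in ("first_mating_ok", "second_mating_ok"):
        df[col] = df[col].map(_parse_bool)
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 1
            raise ValidationError(
                f"double-mating table {path}: non-boolean {col!r} on row {row}"
            )
        df[col] = df[col].astype(bool)
    return df


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(token):
    if isinstance(token, bool):
        return token
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    return _BOOL_MAP.get(str(token).strip().lower(), np.nan)


def read_expression(
    values_path: str | Path,
    sample_sheet_path: str | Path,
    raw_counts: bool = False,
) -> ExpressionData:
    """Read a gene x sample matrix (TSV, first column = gene id) plus its
    sample sheet (TSV: sample, sex, regime, line).

    With ``raw_counts=True`` the matrix is stored as raw counts with library
    sizes taken as column sums; otherwise it is taken as already-normalized
    values.
    """
    mat = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    _require_columns(meta, ["sample", "sex", "regime", "line"], f"sample sheet {sample_sheet_path}")
    meta = meta[["sample", "sex", "regime", "line"]].set_index("sample")
    check_sex(meta["sex"])
    check_regime(meta["regime"])
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise SchemaError(f"sample sheet {sample_sheet_path}: no metadata for sample(s) {missing}")
    meta = meta.loc[list(mat.columns)]
    if raw_counts:
        counts = mat.astype(float)
        return ExpressionData(
            values=None,
            sample_meta=meta,
            raw_counts=counts,
            library_sizes=counts.sum(axis=0),
        )
    return ExpressionData(values=mat.astype(float), sample_meta=meta)


def read_gene_set(path: str | Path) -> list[str]:
    """Read a gene set: one identifier per line, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular homology-search output (BLAST outfmt 6).

    Whitespace- or tab-delimited; every row must have exactly 12 fields.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 12:
                raise ValidationError(
                    f"homology table {path}: row {i} has {len(fields)} fields, expected 12"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    if df.empty:
        return df
    for col in ("percent_identity", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("alignment_length", "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end"):
        df[col] = df[col].astype(int)
    bad_pid = (df["percent_identity"] < 0) | (df["percent_identity"] > 100)
    if bad_pid.any():
        row = int(np.flatnonzero(bad_pid.to_numpy())[0]) + 1
        raise ValidationError(f"homology table {path}: percent identity outside [0,100] on row {row}")
    if (df["evalue"] < 0).any():
        row = int(np.flatnonzero((df["evalue"] < 0).to_numpy())[0]) + 1
        raise ValidationError(f"homology table {path}: negative e-value on row {row}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a result table as delimited text (no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def write_expression(data: ExpressionData, values_path: str | Path, sample_sheet_path: str | Path) -> None:
    """Write an expression matrix (TSV) and its sample sheet (TSV)."""
    mat = data.values if data.values is not None else data.raw_counts
    Path(values_path).parent.mkdir(parents=True, exist_ok=True)
    mat.to_csv(values_path, sep="\t", index_label="gene_id")
    meta = data.sample_meta.reset_index().rename(columns={"index": "sample"})
    if "sample" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample"})
    meta.to_csv(sample_sheet_path, sep="\t", index=False)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
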