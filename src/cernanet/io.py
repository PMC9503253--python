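"""TSV readers and writers.

All tabular artifacts are tab-delimited UTF-8 with a header row and '.'
decimals; CRLF input is accepted.  Expression matrices are written features
x samples with the feature ID in the first column (``feature_id``).  Floats
keep 12 significant digits so write/read round-trips are numerically
faithful.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix, validate_sample_sheet

FLOAT_FORMAT = "%.12g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_expression(m: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    return path


def read_expression(
    path: str | Path, feature_class: str, kind: str, is_log2: bool = False
) -> ExpressionMatrix:
    """Read a feature x sample TSV into an :class:`ExpressionMatrix`.

    Schema violations (duplicate IDs, non-numeric cells) raise with the
    offending identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    try:
        values = df.astype(np.int64 if kind == "count" else float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric expression values ({exc})")
    return ExpressionMatrix(values, feature_class=feature_class, kind=kind,
                            is_log2=is_log2)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return validate_sample_sheet(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")


def read_pairs(path: str | Path, col_a: str, col_b: str) -> pd.DataFrame:
    """Read a two-ID pair table (e.g. co-expressed or DB-constrained pairs)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (col_a, col_b) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.duplicated([col_a, col_b]).any():
        df = df.drop_duplicates([col_a, col_b]).reset_index(drop=True)
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ("feature_id", "fc", "p", "passes")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValidationError(f"{path}: duplicated feature IDs {dups}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    from .validation import validate_ct_table

    df = pd.read_csv(path, sep="\t")
    df["ct_target"] = df["ct_target"].astype(float)
    df["ct_reference"] = df["ct_reference"].astype(float)
    return validate_ct_table(df)
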