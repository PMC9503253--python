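"""Expression matrices and sample sheets.

The central container is :class:`ExpressionMatrix`: a feature x sample table
of non-negative values together with the feature class (lncRNA, mRNA or
miRNA) and the measurement kind (microarray ``intensity`` or sequencing
``count``).  Downstream statistics (t-tests, Pearson correlation) operate on
the log2 scale; ``is_log2`` records whether the stored values are already
log-transformed so that a matrix is never logged twice.

A sample sheet is a plain :class:`pandas.DataFrame` with columns
``sample_id``, ``group`` (``case`` or ``control``) and ``pair_id``; matched
case/control samples share a ``pair_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

FEATURE_CLASSES = ("lncRNA", "mRNA", "miRNA")
KINDS = ("intensity", "count")
GROUPS = ("case", "control")

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "pair_id")


@dataclass
class ExpressionMatrix:
    """Feature x sample expression table with class and measurement kind.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
    feature_class
        One of ``lncRNA``, ``mRNA``, ``miRNA``.
    kind
        ``intensity`` (non-negative reals) or ``count`` (non-negative ints).
    is_log2
        True when the stored values are already on the log2 scale (e.g. the
        output of CPM normalization).  Count matrices are never log-scale.
    """

    values: pd.DataFrame
    feature_class: str
    kind: str
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if self.kind not in KINDS:
            raise ValidationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not self.is_log2 and np.any(arr < 0):
            raise ValidationError("expression values must be non-negative")
        if self.kind == "count":
            if self.is_log2:
                raise ValidationError("count matrices cannot be log2-scale")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("count matrices must hold integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def as_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (no-op if already log2).

        Intensity values must be strictly positive; counts should go through
        CPM normalization instead.
        """
        if self.is_log2:
            return self
        if self.kind == "count":
            raise ValidationError(
                "cannot log-transform raw counts directly; use cpm_normalize"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr <= 0):
            raise ValidationError("log2 transform requires strictly positive values")
        return replace(self, values=np.log2(self.values.astype(float)), is_log2=True)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise ValidationError(f"unknown feature IDs: {missing}")
        return replace(self, values=self.values.loc[list(feature_ids)])


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample sheet.

    Requires columns sample_id / group / pair_id, unique sample IDs and
    groups restricted to ``case`` / ``control``.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample ID: {dups}")
    bad = sorted(set(sheet["group"]) - set(GROUPS))
    if bad:
        raise ValidationError(f"sample sheet groups must be in {GROUPS}, got {bad}")
    return sheet.reset_index(drop=True)


def paired_sample_order(sheet: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Case and control sample IDs aligned by pair_id.

    Raises if any pair does not have exactly one case and one control.
    """
    sheet = validate_sample_sheet(sheet)
    cases, controls = [], []
    for pair_id, grp in sheet.groupby("pair_id", sort=True):
        case = grp.loc[grp["group"] == "case", "sample_id"].tolist()
        ctrl = grp.loc[grp["group"] == "control", "sample_id"].tolist()
        if len(case) != 1 or len(ctrl) != 1:
            raise ValidationError(
                f"pair {pair_id!r} must have exactly one case and one control "
                f"(found {len(case)} case, {len(ctrl)} control)"
            )
        cases.append(case[0])
        controls.append(ctrl[0])
    return cases, controls


def group_samples(sheet: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Case and control sample IDs (unpaired)."""
    sheet = validate_sample_sheet(sheet)
    cases = sheet.loc[sheet["group"] == "case", "sample_id"].tolist()
    controls = sheet.loc[sheet["group"] == "control", "sample_id"].tolist()
    return cases, controls
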