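"""Pearson co-expression screening of DE lncRNA-mRNA pairs.

In a ceRNA relationship the lncRNA and the mRNA compete for the same miRNA,
so their expression moves together; candidate pairs are therefore required
to be *positively* co-expressed.  The screen scores every DE-lncRNA x
DE-mRNA combination across all samples (cases and controls pooled — with
only a few samples per group, within-group correlation is not estimable)
and keeps pairs with signed r >= r_min and two-sided p < p_max.  The
p-value is the usual t-transform of r with n-2 degrees of freedom.

Raw p-values are used, with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("lncrna_id", "mrna_id", "r", "p", "n_samples")


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided p-value.

    Requires n >= 3 and non-zero variance in both vectors; the p-value is
    the t-transform t = r*sqrt((n-2)/(1-r^2)) referred to the t distribution
    with n-2 df (the exact null distribution under bivariate normality).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _log_scale_values(m: ExpressionMatrix) -> pd.DataFrame:
    return m.as_log2().values if not m.is_log2 else m.values


def correlation_table(
    a_expr: ExpressionMatrix,
    b_expr: ExpressionMatrix,
    a_ids: Iterable[str],
    b_ids: Iterable[str],
    col_a: str = "id_a",
    col_b: str = "id_b",
) -> pd.DataFrame:
    """All pairwise Pearson correlations between two feature sets.

    Both matrices must share identical sample columns; correlations are
    computed on log2-scale values.  Zero-variance features are skipped with
    a log entry.  Returns columns col_a, col_b, r, p, n_samples (unfiltered).
    """
    if list(a_expr.sample_ids) != list(b_expr.sample_ids):
        offending = sorted(
            set(a_expr.sample_ids).symmetric_difference(b_expr.sample_ids)
        )
        raise ValidationError(
            "sample columns differ between matrices; offending IDs: "
            f"{offending if offending else 'same set, different order'}"
        )
    a_vals = _log_scale_values(a_expr.subset(list(a_ids)))
    b_vals = _log_scale_values(b_expr.subset(list(b_ids)))
    n = a_vals.shape[1]
    if n < 3:
        raise ValidationError("correlation needs >= 3 samples")

    def standardize(df: pd.DataFrame, label: str) -> pd.DataFrame:
        sd = df.std(axis=1, ddof=1)
        flat = sd.index[np.isclose(sd, 0.0)].tolist()
        if flat:
            logger.info("skipping zero-variance %s features: %s", label, flat)
            df = df.drop(index=flat)
            sd = sd.drop(index=flat)
        centered = df.sub(df.mean(axis=1), axis=0)
        return centered.div(sd, axis=0)

    az = standardize(a_vals, col_a)
    bz = standardize(b_vals, col_b)
    if az.empty or bz.empty:
        return pd.DataFrame(columns=[col_a, col_b, "r", "p", "n_samples"])
    r = az.to_numpy() @ bz.to_numpy().T / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    ia, ib = np.meshgrid(np.arange(len(az)), np.arange(len(bz)), indexing="ij")
    return pd.DataFrame(
        {
            col_a: az.index.to_numpy()[ia.ravel()],
            col_b: bz.index.to_numpy()[ib.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
            "n_samples": n,
        }
    )


def coexpressed_pairs(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    de_lnc: Iterable[str],
    de_genes: Iterable[str],
    r_min: float = 0.9,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Positively co-expressed DE lncRNA-mRNA pairs.

    Scores every DE-lncRNA x DE-mRNA combination and returns those with
    signed r >= r_min and p < p_max, as a DataFrame with columns lncrna_id,
    mrna_id, r, p, n_samples.  Empty DE lists yield an empty table.
    """
    de_lnc, de_genes = list(de_lnc), list(de_genes)
    if not de_lnc or not de_genes:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))
    table = correlation_table(
        lnc_expr, mrna_expr, de_lnc, de_genes, "lncrna_id", "mrna_id"
    )
    if table.empty:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))
    keep = (table["r"] >= r_min) & (table["p"] < p_max)
    return (
        table.loc[keep]
        .sort_values(["lncrna_id", "mrna_id"])
        .reset_index(drop=True)
    )
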