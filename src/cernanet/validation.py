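"""qPCR relative quantification (2^-ddCt) and the Mann-Whitney U test.

Relative expression follows the standard comparative-Ct scheme: per sample,
dCt = Ct(target) - Ct(reference gene); ddCt subtracts the arithmetic mean
dCt of the calibrator group (equivalently, expression is normalized to the
calibrator's geometric mean); relative quantity RQ = 2^-ddCt.  The
calibrator group therefore has geometric-mean RQ exactly 1.

Group comparison uses the Mann-Whitney U test.  For small samples
(combined n <= 20) the null distribution of U is enumerated exactly over
all group assignments of the pooled observations, which handles ties
correctly; the two-sided p is twice the smaller one-sided tail, capped at
1.  Larger samples use the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CT_COLUMNS = ("sample_id", "group", "ct_target", "ct_reference")

EXACT_LIMIT = 20  # combined sample size up to which U is enumerated exactly


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 45):
            raise ValidationError(f"{col} values must lie in (0, 45]")
    return table.reset_index(drop=True)


def ddct_relative_expression(
    table: pd.DataFrame, calibrator_group: str = "control"
) -> pd.DataFrame:
    """Per-sample 2^-ddCt relative expression.

    Returns the input with added columns ``dct``, ``ddct`` and
    ``rel_expr``; the calibrator group's mean dCt is the reference point, so
    its rel_expr values have geometric mean 1.
    """
    table = validate_ct_table(table)
    if not (table["group"] == calibrator_group).any():
        raise ValidationError(f"calibrator group {calibrator_group!r} is empty")
    out = table.copy()
    out["dct"] = out["ct_target"].astype(float) - out["ct_reference"].astype(float)
    calib_mean = out.loc[out["group"] == calibrator_group, "dct"].mean()
    out["ddct"] = out["dct"] - calib_mean
    out["rel_expr"] = 2.0 ** (-out["ddct"])
    return out


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the permutation null for combined n <= 20 (ties
    handled via average ranks); normal approximation with tie correction
    otherwise.  The exact two-sided p doubles the smaller tail
    P(U <= u_obs) / P(U >= u_obs), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_x], n_x)

    if n_x + n_y <= EXACT_LIMIT:
        total = comb(n_x + n_y, n_x)
        n_le = n_ge = 0
        eps = 1e-9
        for idx in combinations(range(n_x + n_y), n_x):
            u = _u_statistic(ranks[list(idx)], n_x)
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return MannWhitneyResult(u=u_obs, p=p, method="exact")

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             method="asymptotic")


def compare_groups(
    rq_table: pd.DataFrame, case_group: str = "case", control_group: str = "control"
) -> dict:
    """Compare relative expression between two groups.

    Emits both the Mann-Whitney p (primary, no distributional assumption)
    and Welch's t p on log2 relative expression, plus group medians.
    """
    x = rq_table.loc[rq_table["group"] == case_group, "rel_expr"].to_numpy(float)
    y = rq_table.loc[rq_table["group"] == control_group, "rel_expr"].to_numpy(float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both comparison groups must be non-empty")
    mw = mann_whitney(x, y)
    t_p = float(stats.ttest_ind(np.log2(x), np.log2(y), equal_var=False).pvalue)
    return {
        "n_case": int(x.size),
        "n_control": int(y.size),
        "median_case": float(np.median(x)),
        "median_control": float(np.median(y)),
        "mannwhitney_u": mw.u,
        "mannwhitney_p": mw.p,
        "mannwhitney_method": mw.method,
        "welch_t_p_log2": t_p,
    }
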