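"""Differential expression for intensity (microarray) and count data.

The screening rule throughout is the classic two-threshold filter: linear
fold change FC >= 1.5 together with a raw two-sided p < 0.05.  Intensities
are quantile-normalized, log2-transformed, and tested with a paired t-test
across matched case/control pairs (Welch's unpaired t is available).  miRNA
counts are CPM-normalized and tested on log2(CPM+1) with the same machinery;
an exact per-feature binomial test conditional on library sizes is available
for very small cohorts.

Fold change is reported on the linear scale as max(case/control,
control/case) >= 1 with a direction, the convention used when screening
lists are published as "FC >= 1.5, up/down".  Features that cannot be tested
(non-positive group mean, zero variance of paired differences) are flagged
rather than raising, and a log entry records each exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ExpressionMatrix, group_samples, paired_sample_order

logger = logging.getLogger(__name__)

DE_COLUMNS = (
    "feature_id",
    "feature_class",
    "mean_case",
    "mean_control",
    "fc",
    "direction",
    "p",
    "passes",
    "untestable",
    "note",
)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an intensity matrix.

    Every column is mapped onto the common reference distribution formed by
    the row-wise mean of the sorted columns, so all columns share identical
    sorted values.  Ties within a column receive the mean of the quantile
    values they span (average ranks, linearly interpolated).
    """
    if m.kind != "intensity":
        raise ValidationError("quantile normalization applies to intensity data")
    if m.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values)


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_map: pd.DataFrame, method: str = "median"
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per transcript.

    ``probe_map`` must map every probe (columns probe_id, transcript_id) to
    exactly one transcript; ``method`` is ``median`` (default) or ``mean``
    over a transcript's probes, per sample.
    """
    if method not in ("median", "mean"):
        raise ValidationError("method must be 'median' or 'mean'")
    mapping = probe_map.set_index("probe_id")["transcript_id"]
    unmapped = [p for p in probe_matrix.feature_ids if p not in mapping.index]
    if unmapped:
        raise ValidationError(f"unmapped probe IDs: {unmapped[:5]}")
    groups = probe_matrix.values.groupby(
        mapping.reindex(probe_matrix.feature_ids).to_numpy(), sort=False
    )
    collapsed = groups.median() if method == "median" else groups.mean()
    collapsed.index.name = probe_matrix.values.index.name
    return replace(probe_matrix, values=collapsed)


def fold_change(case_mean: float, control_mean: float) -> tuple[float, str]:
    """Linear fold change and direction from group means.

    FC = max(case/control, control/case) >= 1; equal means give (1.0, 'up')
    by the tie rule.  Non-positive means are the caller's responsibility
    (flagged untestable upstream) and raise here.
    """
    if case_mean <= 0 or control_mean <= 0:
        raise ValidationError("fold change requires positive group means")
    if case_mean >= control_mean:
        return case_mean / control_mean, "up"
    return control_mean / case_mean, "down"


def _finish_de_table(
    feature_ids,
    feature_class: str,
    mean_case: np.ndarray,
    mean_control: np.ndarray,
    p: np.ndarray,
    notes: list[str],
    fc_threshold: float,
    p_threshold: float,
    adjust: str,
) -> pd.DataFrame:
    fc = np.full(len(feature_ids), np.nan)
    direction = np.array([""] * len(feature_ids), dtype=object)
    untestable = np.array([n != "" and "untestable" in n for n in notes])
    for i in range(len(feature_ids)):
        if untestable[i]:
            continue
        fc[i], direction[i] = fold_change(mean_case[i], mean_control[i])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(p)
        if ok.any():
            p = p.copy()
            p[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif adjust != "none":
        raise ValidationError("adjust must be 'none' or 'bh'")
    passes = (~untestable) & (fc >= fc_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "feature_class": feature_class,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fc": fc,
            "direction": direction,
            "p": p,
            "passes": passes,
            "untestable": untestable,
            "note": notes,
        }
    )


def de_filter_array(
    m: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    paired: bool = True,
    adjust: str = "none",
) -> pd.DataFrame:
    """Differential expression on a (normalized) intensity matrix.

    Fold change uses linear-scale group means; the p-value comes from a
    two-sided paired t-test on log2 intensities across matched pairs
    (``paired=False`` switches to Welch's t).  A feature passes iff
    FC >= fc_threshold and p < p_threshold.
    """
    if m.kind != "intensity":
        raise ValidationError("de_filter_array expects intensity data")
    linear = m.values if not m.is_log2 else 2.0 ** m.values
    log2v = m.as_log2().values if not m.is_log2 else m.values

    if paired:
        cases, controls = paired_sample_order(sample_sheet)
        if len(cases) < 2:
            raise ValidationError("paired t-test needs >= 2 pairs")
    else:
        cases, controls = group_samples(sample_sheet)
        if len(cases) < 2 or len(controls) < 2:
            raise ValidationError("Welch t-test needs >= 2 samples per group")

    mean_case = linear[cases].mean(axis=1).to_numpy()
    mean_control = linear[controls].mean(axis=1).to_numpy()

    n_feat = m.n_features
    p = np.full(n_feat, np.nan)
    notes = [""] * n_feat
    ca = log2v[cases].to_numpy()
    co = log2v[controls].to_numpy()
    for i, fid in enumerate(m.feature_ids):
        if mean_case[i] <= 0 or mean_control[i] <= 0:
            notes[i] = "untestable: non-positive group mean"
            logger.info("excluding %s: non-positive group mean", fid)
            continue
        if paired:
            diffs = ca[i] - co[i]
            if np.allclose(diffs.std(ddof=1), 0.0):
                p[i] = 1.0
                notes[i] = "zero variance of paired differences"
                logger.info("feature %s: zero-variance paired differences, p=1", fid)
                continue
            p[i] = stats.ttest_rel(ca[i], co[i]).pvalue
        else:
            if np.allclose(ca[i].std(ddof=1), 0.0) and np.allclose(
                co[i].std(ddof=1), 0.0
            ):
                p[i] = 1.0 if np.isclose(ca[i].mean(), co[i].mean()) else 0.0
                notes[i] = "zero within-group variance"
                continue
            p[i] = stats.ttest_ind(ca[i], co[i], equal_var=False).pvalue
    return _finish_de_table(
        m.feature_ids, m.feature_class, mean_case, mean_control, p, notes,
        fc_threshold, p_threshold, adjust,
    )


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization followed by log2(x+1).

    The result is stored as an intensity-kind, log2-scale matrix so that it
    can enter the same correlation and testing machinery as the arrays.
    """
    if m.kind != "count":
        raise ValidationError("cpm_normalize expects count data")
    lib = m.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    cpm = m.values * 1e6 / lib
    return ExpressionMatrix(
        np.log2(cpm + 1.0), feature_class=m.feature_class, kind="intensity",
        is_log2=True,
    )


def de_filter_counts(
    m: ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    paired: bool = True,
    method: str = "t",
    adjust: str = "none",
) -> pd.DataFrame:
    """Differential expression on a count matrix.

    Fold change is computed on CPM group means.  ``method='t'`` (default)
    tests log2(CPM+1) with the paired (or Welch) t-test; ``method='binomial'``
    runs, per feature, an exact two-sided binomial test of the pooled case
    count against the case library-size fraction — usable at very small n
    where the t-test has almost no power.  The method used is recorded in
    the ``note`` column.
    """
    if m.kind != "count":
        raise ValidationError("de_filter_counts expects count data")
    if method not in ("t", "binomial"):
        raise ValidationError("method must be 't' or 'binomial'")
    cases, controls = group_samples(sample_sheet)
    if not cases or not controls:
        raise ValidationError("both groups must be non-empty")

    lib = m.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    cpm = m.values * 1e6 / lib
    mean_case = cpm[cases].mean(axis=1).to_numpy()
    mean_control = cpm[controls].mean(axis=1).to_numpy()

    if method == "t":
        logm = ExpressionMatrix(
            np.log2(cpm + 1.0), m.feature_class, "intensity", is_log2=True
        )
        table = de_filter_array(
            logm, sample_sheet, fc_threshold, p_threshold, paired=paired,
            adjust=adjust,
        )
        # FC must come from CPM means, not from 2**mean(log2(CPM+1))
        table["mean_case"] = mean_case
        table["mean_control"] = mean_control
        for i in range(len(table)):
            if table.at[i, "untestable"]:
                continue
            if mean_case[i] <= 0 or mean_control[i] <= 0:
                table.at[i, "untestable"] = True
                table.at[i, "note"] = "untestable: zero CPM group mean"
                table.at[i, "fc"] = np.nan
                table.at[i, "direction"] = ""
                logger.info(
                    "excluding %s: zero CPM group mean", table.at[i, "feature_id"]
                )
                continue
            fc, d = fold_change(mean_case[i], mean_control[i])
            table.at[i, "fc"], table.at[i, "direction"] = fc, d
        table["passes"] = (
            ~table["untestable"]
            & (table["fc"] >= fc_threshold)
            & (table["p"] < p_threshold)
        )
        table["note"] = [
            (n + "; " if n else "") + "test=paired-t-logCPM"
            if paired
            else (n + "; " if n else "") + "test=welch-t-logCPM"
            for n in table["note"]
        ]
        return table

    # Exact conditional binomial: pooled case count k out of k+l events,
    # success probability = case library fraction.
    n_feat = m.n_features
    p = np.full(n_feat, np.nan)
    notes = ["test=binomial-conditional"] * n_feat
    lib_case = float(lib[cases].sum())
    lib_total = float(lib[cases].sum() + lib[controls].sum())
    prob = lib_case / lib_total
    counts_case = m.values[cases].sum(axis=1).to_numpy()
    counts_total = counts_case + m.values[controls].sum(axis=1).to_numpy()
    for i in range(n_feat):
        if mean_case[i] <= 0 or mean_control[i] <= 0:
            notes[i] = "untestable: non-positive group mean"
            logger.info("excluding %s: non-positive CPM mean", m.feature_ids[i])
            continue
        p[i] = stats.binomtest(
            int(counts_case[i]), int(counts_total[i]), prob
        ).pvalue
    return _finish_de_table(
        m.feature_ids, m.feature_class, mean_case, mean_control, p, notes,
        fc_threshold, p_threshold, adjust,
    )


def passing_features(de_table: pd.DataFrame) -> list[str]:
    """Feature IDs that pass the DE filter, in table order."""
    return de_table.loc[de_table["passes"], "feature_id"].tolist()
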