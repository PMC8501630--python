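"""Two-group comparison of complexity scores with Bonferroni correction.

Group means are compared with Welch's t-test unless a Shapiro-Wilk test
(alpha = 0.01) flags a strong deviation from normality in either group, in
which case the Wilcoxon rank-sum (Mann-Whitney) test is used.  Scores may
first be residualized on per-sample covariates (ploidy, aberrant cell
fraction) by ordinary least squares.  P-values are Bonferroni-corrected
within the family of all scores tested in a mode: m = 8 genome-wide, or
8 x (number of arms) arm-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ascopy")

__all__ = [
    "ComparisonResult",
    "select_test",
    "adjust_scores",
    "compare_groups",
    "results_to_frame",
    "write_results",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One score's two-group comparison."""

    score_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str  # "t" (Welch) or "wilcoxon"
    p_raw: float
    p_adjusted: float
    m: int
    neg_log10_p: float
    direction: str  # e.g. "groupA>groupB"
    significant: bool


def select_test(group_a: Sequence[float], group_b: Sequence[float],
                alpha: float = 0.01) -> str:
    """Choose "t" (Welch) or "wilcoxon" by Shapiro-Wilk normality screening."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 observations")
    for g in (a, b):
        # Shapiro-Wilk is undefined for constant input; a point mass is as
        # non-normal as it gets, so route to the rank test.
        if np.ptp(g) == 0:
            return "wilcoxon"
        if stats.shapiro(g).pvalue < alpha:
            return "wilcoxon"
    return "t"


def adjust_scores(scores: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize each score column on the covariates (plus intercept).

    *scores*: samples x score columns.  *covariates*: samples x covariate
    columns (e.g. ploidy, acf).  Samples missing a covariate are dropped
    (logged); constant covariates are dropped with a warning.  Each
    returned column has mean ~0.
    """
    cov = covariates.reindex(scores.index).astype(float)
    complete = cov.notna().all(axis=1)
    if not complete.all():
        dropped = list(scores.index[~complete])
        logger.warning("adjust_scores: dropping %d samples with missing covariates: %s",
                       len(dropped), dropped[:5])
    cov = cov.loc[complete]
    sub = scores.loc[complete].astype(float)

    keep_cols = []
    for col in cov.columns:
        if np.ptp(cov[col].to_numpy()) == 0:
            logger.warning("adjust_scores: covariate %r is constant, dropped", col)
        else:
            keep_cols.append(col)
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy() for c in keep_cols])

    out = {}
    for col in sub.columns:
        y = sub[col].to_numpy()
        ok = ~np.isnan(y)
        resid = np.full(len(y), np.nan)
        if ok.sum() > X.shape[1]:
            beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
            resid[ok] = y[ok] - X[ok] @ beta
        out[col] = resid
    return pd.DataFrame(out, index=sub.index)


def compare_groups(
    scores: pd.DataFrame,
    grouping: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_group: int = 3,
) -> list[ComparisonResult]:
    """Compare every score column between the two groups in *grouping*.

    *grouping* maps sample -> label; samples labelled NaN/"unknown" are
    dropped; exactly two labels must remain.  The Bonferroni family size m
    is the number of score columns (8 genome-wide, 8 x arms arm-wise).
    Score columns where either group has fewer than *min_group* non-missing
    values are skipped with a warning.
    """
    g = grouping.reindex(scores.index).astype("object")
    g = g[g.notna() & (g.astype(str).str.lower() != "unknown")]
    labels = sorted(map(str, g.unique()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups after dropping unknowns, got {labels}")
    la, lb = labels
    idx_a = g.index[g.astype(str) == la]
    idx_b = g.index[g.astype(str) == lb]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("one comparison group is empty")

    data = scores
    if covariates is not None:
        data = adjust_scores(scores, covariates)

    m = data.shape[1]
    results: list[ComparisonResult] = []
    for col in data.columns:
        va = data.loc[idx_a, col].dropna().to_numpy(dtype=float)
        vb = data.loc[idx_b, col].dropna().to_numpy(dtype=float)
        if len(va) < min_group or len(vb) < min_group:
            logger.warning("compare_groups: %r skipped (group sizes %d/%d < %d)",
                           col, len(va), len(vb), min_group)
            continue
        test = select_test(va, vb)
        if test == "t":
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        if np.isnan(p):  # identical constant groups
            p = 1.0
        p_adj = min(1.0, m * p)
        direction = f"{la}>{lb}" if va.mean() > vb.mean() else f"{lb}>{la}"
        results.append(ComparisonResult(
            score_id=str(col), group_a=la, group_b=lb, n_a=len(va), n_b=len(vb),
            test=test, p_raw=p, p_adjusted=p_adj, m=m,
            neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
            direction=direction, significant=p_adj < alpha,
        ))
    return results


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    rows = [
        (r.score_id, r.group_a, r.group_b, r.n_a, r.n_b, r.test, r.p_raw,
         r.p_adjusted, r.m, r.neg_log10_p, r.direction, r.significant)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "score", "group_a", "group_b", "n_a", "n_b", "test", "p_raw",
        "p_adjusted", "m", "neg_log10_p", "direction", "significant",
    ])


def write_results(results: Iterable[ComparisonResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
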