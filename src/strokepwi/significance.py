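"""Normalization and the Levene-gated two-sample t-test filter that keeps
features significantly different between lesion (LT) and normal (NT) rows.

The normalization is range scaling of the centered values,
``F* = (F - mean(F)) / (max(F) - min(F))``; an alternative z-score mode is
available for sensitivity analysis.  For each feature a Levene test (mean
centered) decides between the pooled-variance and Welch t-test branches;
features with a two-sided t-test p < alpha are retained.  No
multiple-testing correction is applied (raw p-value filtering is the
procedure being reproduced; an FDR variant would change the retained set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import TemporalFeatureTable

__all__ = [
    "normalize", "normalize_frame", "variance_gate", "two_sample_t",
    "filter_significant", "SignificanceResult",
]

log = logging.getLogger(__name__)


@dataclass
class SignificanceResult:
    """Per-feature test summary: Levene p, chosen branch, t-test p, verdict."""

    table: pd.DataFrame           # columns: feature, levene_p, equal_var, t_p, significant
    alpha: float


def normalize(values, mode: str = "range") -> np.ndarray:
    """Center on the mean and scale: by the range (``(x - mean)/(max - min)``,
    default) or to unit variance (``mode='zscore'``).  Constant features map
    to all-zeros by convention."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    centered = x - x.mean()
    denom = (x.max() - x.min()) if mode == "range" else x.std()
    if denom <= 0:
        return np.zeros_like(x)
    return centered / denom


def normalize_frame(df: pd.DataFrame, mode: str = "range") -> pd.DataFrame:
    out = {c: normalize(df[c].to_numpy(), mode=mode) for c in df.columns}
    return pd.DataFrame(out, columns=df.columns, index=df.index)


def variance_gate(x, y, alpha: float = 0.05) -> tuple:
    """Levene homogeneity-of-variance test (mean-centered variant).

    Returns ``(equal_var, p)`` with ``equal_var = (p >= alpha)``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return True, 1.0          # both degenerate: variances trivially equal
    _, p = stats.levene(x, y, center="mean")
    if np.isnan(p):
        p = 1.0
    return bool(p >= alpha), float(p)


def two_sample_t(x, y, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value: pooled variance when
    ``equal_var``, Welch (Satterthwaite df) otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):
        # zero variance in both groups: identical means are maximally
        # non-significant, different means maximally significant
        return 1.0 if x.mean() == y.mean() else 0.0
    return p


def filter_significant(table: TemporalFeatureTable | pd.DataFrame,
                       labels=None, alpha: float = 0.05,
                       norm_mode: str = "range") -> tuple:
    """Normalize every feature, test LT vs NT, keep columns with t_p < alpha.

    ``labels`` is the 0/1 tissue coding (NT=0, LT=1); when ``table`` is a
    TemporalFeatureTable it defaults to the row metadata.  Returns
    ``(SignificanceResult, reduced_values_frame)``.
    """
    if isinstance(table, TemporalFeatureTable):
        values = table.values
        if labels is None:
            labels = table.row_meta["tissue"].to_numpy()
    else:
        values = table
        if labels is None:
            raise ValueError("labels are required for a plain DataFrame")
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both tissue classes (0 and 1) must be present")

    norm = normalize_frame(values, mode=norm_mode)
    a = norm.loc[labels == 1]
    b = norm.loc[labels == 0]
    records = []
    for col in norm.columns:
        xv, yv = a[col].to_numpy(), b[col].to_numpy()
        equal_var, lev_p = variance_gate(xv, yv, alpha)
        t_p = two_sample_t(xv, yv, equal_var=equal_var)
        records.append((col, lev_p, equal_var, t_p, t_p < alpha))
    res = pd.DataFrame(records, columns=["feature", "levene_p", "equal_var",
                                         "t_p", "significant"])
    kept = res.loc[res["significant"], "feature"].tolist()
    if not kept:
        log.warning("no features passed the significance filter "
                    "(alpha=%.3g)", alpha)
    return SignificanceResult(table=res, alpha=alpha), norm[kept]
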