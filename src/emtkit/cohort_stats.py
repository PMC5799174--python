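"""Cohort-level statistics for the TMA quantification tables.

Covers the statistical layer of the tissue analysis: Pearson/Spearman
marker correlations within a compartment, benign-vs-cancer comparison by
Welch's (unequal-variance) one-way ANOVA with the percent difference
relative to the benign mean, Shapiro-Wilk normality testing, and Pearson
chi-square (no continuity correction) on score x clinicopathology
cross-tabulations.  All p-values are two-sided and no multiple-testing
correction is applied at this layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import DegenerateInputError


@dataclass
class StatResult:
    statistic: float
    p: float
    method: str
    df: Optional[Tuple[float, ...]] = None
    extra: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of [0,1]: {self.p}")


def _check_not_constant(x: np.ndarray, what: str) -> None:
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{what} is constant; statistic undefined")


def marker_correlation(
    quant: pd.DataFrame,
    compartment: str,
    marker_x: str,
    marker_y: str,
    method: str = "pearson",
    value_col: str = "alpha",
    region_cols: Sequence[str] = ("patient_id", "core_id", "region_id"),
) -> StatResult:
    """Correlate two markers across regions of one compartment.

    ``quant`` is the tidy quantification table (one row per region x
    compartment x marker); rows are paired on the region identifier columns.
    """
    sub = quant[quant["compartment"] == compartment]
    keys = [c for c in region_cols if c in sub.columns]
    wide = sub.pivot_table(
        index=keys, columns="marker", values=value_col
    ).dropna(subset=[marker_x, marker_y])
    x = wide[marker_x].to_numpy(dtype=float)
    y = wide[marker_y].to_numpy(dtype=float)
    return paired_correlation(x, y, method=method)


def paired_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    _check_not_constant(x, "x")
    _check_not_constant(y, "y")
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return StatResult(float(res.statistic), float(res.pvalue), "pearson",
                          df=(float(x.size - 2),))
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return StatResult(float(rho), float(p), "spearman")
    raise ValueError(f"unknown correlation method {method!r}")


def welch_anova(groups: Sequence[np.ndarray]) -> StatResult:
    """Welch's one-way ANOVA (unequal variances) for k >= 2 groups.

    Uses the Welch F statistic with Welch-Satterthwaite denominator degrees
    of freedom; for two groups it reduces to the squared Welch t-test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    # noiseless groups: identical means are a perfect null, distinct means
    # perfect separation; a single zero-variance group gets its variance
    # floored relative to the largest group variance
    if v.max() <= np.abs(m).max() * 1e-14:
        if np.ptp(m) == 0:
            return StatResult(0.0, 1.0, "welch-anova",
                              df=(float(k - 1), np.inf))
        return StatResult(np.inf, 0.0, "welch-anova",
                          df=(float(k - 1), np.inf))
    v = np.maximum(v, v.max() * 1e-15)
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = 1.0 + (2.0 * (k - 2) / (k * k - 1.0)) * np.sum(
        (1.0 - w / np.sum(w)) ** 2 / (n - 1)
    )
    f = a / b
    df2 = (k * k - 1.0) / (3.0 * np.sum((1.0 - w / np.sum(w)) ** 2 / (n - 1)))
    p = float(stats.f.sf(f, k - 1, df2))
    return StatResult(float(f), p, "welch-anova", df=(float(k - 1), float(df2)))


def benign_cancer_comparison(
    benign: np.ndarray, cancer: np.ndarray
) -> Tuple[StatResult, float]:
    """Welch one-way ANOVA of cancer vs benign values plus the percent
    difference of means relative to the benign mean."""
    benign = np.asarray(benign, dtype=float)
    cancer = np.asarray(cancer, dtype=float)
    mb = benign.mean()
    if mb == 0:
        raise DegenerateInputError("benign mean is zero: percent undefined")
    result = welch_anova([benign, cancer])
    percent = 100.0 * (cancer.mean() - mb) / mb
    return result, float(percent)


def normality_test(values: np.ndarray) -> StatResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    _check_not_constant(values, "sample")
    w, p = stats.shapiro(values)
    return StatResult(float(w), float(p), "shapiro-wilk")


def crosstab_chi2(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateInputError("zero marginal: expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(float(chi2), float(p), "pearson-chi2", df=(float(df),))


def build_crosstab(
    cohort: pd.DataFrame,
    category_col: str,
    clinical_col: str,
    categories: Sequence[str] = ("Negative", "Weak", "Moderate", "Strong"),
    clinical_groups: Optional[Sequence[str]] = None,
    exclude_col: str = "excluded",
) -> pd.DataFrame:
    """Cross-tabulate score category against a clinical axis after exclusions.

    Patients flagged in ``exclude_col`` (neo-adjuvant therapy, missing
    grade/stage) or missing either variable never enter the table.  Returns
    the count table (clinical groups in rows, categories in columns);
    an all-excluded cohort yields an empty (all-zero-row-free) table.
    """
    df = cohort
    if exclude_col in df.columns:
        df = df[~df[exclude_col].astype(bool)]
    df = df.dropna(subset=[category_col, clinical_col])
    if clinical_groups is None:
        clinical_groups = sorted(df[clinical_col].unique())
    counts = pd.crosstab(df[clinical_col], df[category_col])
    counts = counts.reindex(
        index=list(clinical_groups), columns=list(categories), fill_value=0
    ).fillna(0).astype(int)
    counts = counts.loc[counts.sum(axis=1) > 0]
    return counts
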