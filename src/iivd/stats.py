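"""Two-group comparison engine: t-tests with a variance gate, chi-square,
Cohen's d, Benjamini–Hochberg FDR control, and Pearson correlations.

Test selection for continuous variables follows the variance-gated rule:
an F-test on the two sample variances at p < 0.05 switches from the pooled
two-sample t-test to Welch's t-test (Satterthwaite degrees of freedom).
Cohen's d always uses the pooled SD, even when Welch's statistic is
reported.  Signs follow the group1 − group2 convention.

All statistics are computed from summary statistics (n, mean, SD) so that
printed tables can be recomputed exactly; distribution tail probabilities
come from scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from iivd.errors import DegenerateStatisticError

logger = logging.getLogger(__name__)

_TWO_SIDED_Z95 = 1.959964


def pooled_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    """Two-sample pooled-variance t statistic and its df (n1 + n2 - 2)."""
    _check_t_inputs(n1, n2, s1, s2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, float(df)
        raise DegenerateStatisticError(
            "zero pooled variance with unequal means: t statistic is infinite"
        )
    t = (m1 - m2) / (np.sqrt(sp2) * np.sqrt(1 / n1 + 1 / n2))
    return float(t), float(df)


def welch_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    """Welch's t statistic with Welch–Satterthwaite degrees of freedom."""
    _check_t_inputs(n1, n2, s1, s2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2)
        raise DegenerateStatisticError(
            "zero variance in both groups with unequal means"
        )
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (
        (v1**2 / (n1 - 1) if v1 else 0.0) + (v2**2 / (n2 - 1) if v2 else 0.0)
    )
    return float(t), float(df)


def variance_f_test(s1, n1, s2, n2) -> float:
    """Two-sided p for equality of variances (larger variance on top).

    Zero variance in either group returns p = 0 by convention, forcing the
    Welch branch downstream.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("variance F-test requires n >= 2 per group")
    if s1 == 0 or s2 == 0:
        return 0.0
    if s1**2 >= s2**2:
        f, dfn, dfd = s1**2 / s2**2, n1 - 1, n2 - 1
    else:
        f, dfn, dfd = s2**2 / s1**2, n2 - 1, n1 - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def cohens_d_pooled(m1, s1, n1, m2, s2, n2) -> float:
    """Cohen's d with pooled SD, sign convention group1 - group2."""
    _check_t_inputs(n1, n2, s1, s2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateStatisticError("zero pooled SD: effect size undefined")
    return float((m1 - m2) / np.sqrt(sp2))


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateStatisticError("contingency table has a zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(sps.chi2.sf(stat, df))


def benjamini_hochberg(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR level ``q``.

    Sorted p-values p(1) <= ... <= p(m) are compared with k*q/m; every
    hypothesis with p <= p(k*) for the largest passing rank k* is flagged.
    Ties share their fate and the output preserves the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    passing = p[order] <= (np.arange(1, m + 1) * q / m)
    if not passing.any():
        return np.zeros(m, dtype=bool)
    threshold = p[order][np.nonzero(passing)[0].max()]
    return p <= threshold


def bh_adjust(pvals) -> np.ndarray:
    """BH-adjusted p-values (step-up with monotone enforcement)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("Pearson correlation requires finite values")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = (dx * dx).sum(), (dy * dy).sum()
    if sxx == 0 or syy == 0:
        raise DegenerateStatisticError("zero variance: correlation undefined")
    r = float((dx * dy).sum() / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * sps.t.sf(abs(t), n - 2))


@dataclass
class ComparisonRow:
    """One variable's two-group comparison (Table-1/Table-2 shaped)."""

    variable: str
    test: str  # pooled-t | welch-t | chi-square
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    statistic: float
    df: float
    p_raw: float
    p_adj: float = np.nan
    significant: bool = False
    cohens_d: float = np.nan


def compare_continuous(m1, s1, n1, m2, s2, n2, gate_alpha: float = 0.05):
    """Variance-gated t comparison from summary statistics.

    Returns (test name, t, df, p).  Welch's test is chosen iff the variance
    F-test rejects equality at ``gate_alpha``.
    """
    if s1 == 0 and s2 == 0:
        t, df = pooled_t(m1, s1, n1, m2, s2, n2)
        return "pooled-t", t, df, 1.0
    p_f = variance_f_test(s1, n1, s2, n2)
    if p_f < gate_alpha:
        t, df = welch_t(m1, s1, n1, m2, s2, n2)
        kind = "welch-t"
    else:
        t, df = pooled_t(m1, s1, n1, m2, s2, n2)
        kind = "pooled-t"
    return kind, t, df, float(2 * sps.t.sf(abs(t), df))


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    variables: list[str] | dict[str, str],
    q: float = 0.05,
    group_order: tuple | None = None,
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison report over a family of variables.

    ``variables`` is a list of column names (kind inferred from dtype) or a
    mapping name -> ``"continuous"``/``"categorical"``.  The BH procedure
    is applied across the whole family (one table = one family) at FDR
    level ``q``; the report carries raw p, BH-adjusted p and the flag.
    Group1/group2 follow ``group_order`` (default: sorted labels), and
    signs follow group1 - group2.
    """
    levels = list(group_order) if group_order else sorted(data[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    g1 = data[data[group_col] == levels[0]]
    g2 = data[data[group_col] == levels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")

    if isinstance(variables, dict):
        kinds = dict(variables)
    else:
        kinds = {
            v: ("continuous" if pd.api.types.is_numeric_dtype(data[v]) else "categorical")
            for v in variables
            if v in data.columns
        }

    rows: list[ComparisonRow] = []
    for var, kind in kinds.items():
        if var not in data.columns:
            logger.warning("variable %r absent from table; skipped", var)
            continue
        if kind == "continuous":
            x1 = g1[var].dropna().astype(float)
            x2 = g2[var].dropna().astype(float)
            m1, s1, n1 = x1.mean(), x1.std(ddof=1), len(x1)
            m2, s2, n2 = x2.mean(), x2.std(ddof=1), len(x2)
            test, t, df, p = compare_continuous(m1, s1, n1, m2, s2, n2, gate_alpha)
            d = cohens_d_pooled(m1, s1, n1, m2, s2, n2)
            rows.append(
                ComparisonRow(var, test, n1, n2, m1, s1, m2, s2, t, df, p, cohens_d=d)
            )
        else:
            counts = pd.crosstab(data[group_col], data[var])
            counts = counts.loc[levels]
            stat, df, p = chi_square(counts.to_numpy())
            rows.append(
                ComparisonRow(
                    var, "chi-square", int(counts.iloc[0].sum()),
                    int(counts.iloc[1].sum()),
                    np.nan, np.nan, np.nan, np.nan, stat, float(df), p,
                )
            )

    report = pd.DataFrame([vars(r) for r in rows])
    if len(report):
        report["p_adj"] = bh_adjust(report["p_raw"].to_numpy())
        report["significant"] = benjamini_hochberg(report["p_raw"].to_numpy(), q=q)
    report.attrs["groups"] = tuple(levels)
    report.attrs["fdr_q"] = q
    return report


def correlation_table(
    data: pd.DataFrame, targets: list[str], against: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlations of ``targets`` vs ``against`` columns."""
    rows = []
    for a in targets:
        for b in against:
            sub = data[[a, b]].dropna()
            r, p = pearson_r(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append({"var1": a, "var2": b, "r": r, "n": len(sub), "p_raw": p})
    return pd.DataFrame(rows)


def _check_t_inputs(n1, n2, s1, s2) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample comparisons require n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
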