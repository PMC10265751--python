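"""Case-control descriptive statistics.

Implements the baseline-table layer of a case-control biomarker study:
normality-driven choice between the t-test (mean +/- SD summary) and the
Wilcoxon-Mann-Whitney test (median (IQR) summary) for continuous variables,
the two-proportion z test for binary variables, pairwise-complete Spearman
correlation matrices, and multivariable linear regression of expression on
clinical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportions_ztest

__all__ = ["GroupComparison", "compare_groups", "spearman_matrix", "linear_fit", "describe_cohort"]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_cases: str
    summary_controls: str
    test_used: str  # "t" | "wilcoxon" | "proportion"
    statistic: float
    p_value: float


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk needs >= 3 values and non-constant data
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


def compare_groups(
    values_cases: Sequence[float],
    values_controls: Sequence[float],
    variable: str = "",
    kind: str = "auto",
    alpha_normality: float = 0.05,
    test: str = "auto",
) -> GroupComparison:
    """Compare one variable between cases and controls.

    Continuous variables are screened for normality (Shapiro-Wilk per group);
    both groups normal dispatches to the t-test (pooled or Welch according to
    a Levene variance screen) with a "mean +/- SD" summary, otherwise to the
    Wilcoxon-Mann-Whitney test with a "median (q1-q3)" summary.  Binary 0/1
    variables use the two-proportion z test with an "n (%)" summary.
    The statistic is signed cases-minus-controls.  ``test`` forces the
    continuous branch ("t" or "wilcoxon") past the normality screen.
    """
    x = np.asarray(values_cases, dtype=float)
    y = np.asarray(values_controls, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two non-missing values per group")

    if kind == "auto":
        kind = "binary" if (_is_binary(x) and _is_binary(y)) else "continuous"

    if kind == "binary":
        counts = np.array([x.sum(), y.sum()])
        nobs = np.array([x.size, y.size])
        z, p = proportions_ztest(counts, nobs)
        return GroupComparison(
            variable=variable,
            summary_cases=f"{int(counts[0])} ({100 * counts[0] / nobs[0]:.1f}%)",
            summary_controls=f"{int(counts[1])} ({100 * counts[1] / nobs[1]:.1f}%)",
            test_used="proportion",
            statistic=float(z),
            p_value=float(p),
        )

    use_t = test == "t" if test != "auto" else (
        _shapiro_normal(x, alpha_normality) and _shapiro_normal(y, alpha_normality)
    )
    if use_t:
        equal_var = stats.levene(x, y, center="mean").pvalue >= 0.05
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        return GroupComparison(
            variable=variable,
            summary_cases=f"{x.mean():.3f} ± {x.std(ddof=1):.3f}",
            summary_controls=f"{y.mean():.3f} ± {y.std(ddof=1):.3f}",
            test_used="t",
            statistic=float(t),
            p_value=float(p),
        )

    # Wilcoxon-Mann-Whitney; asymptotic normal approximation with tie and
    # continuity correction (exact enumeration only for small, tie-free data)
    method = "exact" if (x.size <= 25 and y.size <= 25 and np.unique(np.r_[x, y]).size == x.size + y.size) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    mu = x.size * y.size / 2.0
    qx = np.percentile(x, [25, 50, 75])
    qy = np.percentile(y, [25, 50, 75])
    return GroupComparison(
        variable=variable,
        summary_cases=f"{qx[1]:.3f} ({qx[0]:.3f}-{qx[2]:.3f})",
        summary_controls=f"{qy[1]:.3f} ({qy[0]:.3f}-{qy[2]:.3f})",
        test_used="wilcoxon",
        statistic=u - mu,  # signed location of U about its null mean
        p_value=float(res.pvalue),
    )


def spearman_matrix(columns: Mapping[str, Sequence[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix with p-values.

    Returns ``(r, p)`` DataFrames; unit diagonal; pairs with fewer than three
    complete observations or a constant column are reported as NaN.
    """
    names = list(columns)
    data = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    n = len(names)
    r = pd.DataFrame(np.eye(n), index=names, columns=names)
    p = pd.DataFrame(np.zeros((n, n)), index=names, columns=names)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = data[names[i]], data[names[j]]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rij = pij = np.nan
            else:
                res = stats.spearmanr(x[ok], y[ok])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def linear_fit(
    response: Sequence[float],
    design: pd.DataFrame,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Ordinary least squares with two-sided t p-values per coefficient.

    Raises on rank deficiency, naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = design.astype(float).copy()
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # flag columns whose R diagonal vanishes in a QR factorisation
        _, R = np.linalg.qr(X.values)
        diag = np.abs(np.diag(R))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )


def describe_cohort(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Baseline comparison table, one row per variable."""
    is_case = cohort[group_col] == "case"
    rows = []
    for var in variables:
        cmp_ = compare_groups(
            cohort.loc[is_case, var], cohort.loc[~is_case, var],
            variable=var, alpha_normality=alpha_normality,
        )
        rows.append(
            {
                "variable": cmp_.variable,
                "cases": cmp_.summary_cases,
                "controls": cmp_.summary_controls,
                "test": cmp_.test_used,
                "statistic": cmp_.statistic,
                "p": cmp_.p_value,
            }
        )
    return pd.DataFrame(rows)
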