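"""Severity-stratum ANOVA of marker expression.

Cases are grouped by empirical quartiles of an angiographic severity score
(Gensini); expression is compared across the four strata with the classic
one-way F statistic, with Welch and Brown-Forsythe robust variants,
variance-homogeneity screens (Levene mean-centred, Brown-Forsythe
median-centred), and Bonferroni-adjusted pairwise t-tests using the pooled
within-group mean square.

The F statistic can be computed either from raw per-group values or from
sufficient statistics (n, mean, SD) as printed in a summary table; the two
routes agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeverityGroups",
    "AnovaSummary",
    "quartile_groups",
    "anova_oneway",
    "anova_from_summary",
    "bonferroni_posthoc",
]

QUARTILE_LABELS = ("mild", "ordinary", "severe", "critical")


@dataclass(frozen=True)
class SeverityGroups:
    boundaries: tuple[float, float, float]
    labels: pd.Series  # per-subject stratum label, aligned to the input index
    sizes: dict[str, int]


@dataclass(frozen=True)
class AnovaSummary:
    group_n: tuple[int, ...]
    group_mean: tuple[float, ...]
    group_sd: tuple[float, ...]
    f: float
    p: float
    df: tuple[float, float]
    method: str
    levene: tuple[float, float] | None = None
    brown_forsythe: tuple[float, float] | None = None


def quartile_groups(scores: Sequence[float]) -> SeverityGroups:
    """Split subjects into four severity strata at the empirical quartiles.

    Quartiles use the linear-interpolation rule; ties at a boundary are
    assigned to the lower stratum (assignment is ``score <= boundary``).
    Missing scores get no label.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    valid = s.dropna()
    if valid.size < 4:
        raise ValueError("need at least four subjects with severity scores")
    q1, q2, q3 = np.quantile(valid, [0.25, 0.5, 0.75])
    def assign(v: float) -> str:
        if v <= q1:
            return QUARTILE_LABELS[0]
        if v <= q2:
            return QUARTILE_LABELS[1]
        if v <= q3:
            return QUARTILE_LABELS[2]
        return QUARTILE_LABELS[3]
    labels = s.map(lambda v: assign(v) if np.isfinite(v) else None)
    sizes = {lab: int((labels == lab).sum()) for lab in QUARTILE_LABELS}
    return SeverityGroups(boundaries=(float(q1), float(q2), float(q3)), labels=labels, sizes=sizes)


def _group_stats(groups: Sequence[Sequence[float]]):
    arrays = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        a = a[~np.isnan(a)]
        if a.size < 2:
            raise ValueError("each group needs at least two non-missing values")
        arrays.append(a)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n = np.array([a.size for a in arrays])
    m = np.array([a.mean() for a in arrays])
    sd = np.array([a.std(ddof=1) for a in arrays])
    return arrays, n, m, sd


def _classic_f(n: np.ndarray, m: np.ndarray, sd: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    k = n.size
    N = int(n.sum())
    grand = float(np.sum(n * m) / N)
    ms_between = float(np.sum(n * (m - grand) ** 2) / (k - 1))
    ms_within = float(np.sum((n - 1) * sd**2) / (N - k))
    if ms_within == 0.0:
        f = np.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    df = (k - 1.0, float(N - k))
    p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return f, p, df


def anova_oneway(
    groups: Sequence[Sequence[float]],
    method: str = "classic",
    homogeneity: bool = True,
) -> AnovaSummary:
    """One-way ANOVA across groups of raw values.

    ``method``: ``classic`` (pooled-variance F), ``welch``, or
    ``brown-forsythe`` (the robust mean-comparison variant).  Homogeneity
    screens (Levene mean-centred; Brown-Forsythe median-centred) are attached
    unless disabled.
    """
    arrays, n, m, sd = _group_stats(groups)
    if method == "classic":
        f, p, df = _classic_f(n, m, sd)
    elif method == "welch":
        w = n / sd**2
        mw = float(np.sum(w * m) / np.sum(w))
        k = n.size
        num = np.sum(w * (m - mw) ** 2) / (k - 1)
        tmp = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
        den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
        f = float(num / den)
        df2 = float((k**2 - 1) / (3 * tmp))
        df = (k - 1.0, df2)
        p = float(stats.f.sf(f, *df))
    elif method == "brown-forsythe":
        # robust comparison of means with per-group variances (Brown-Forsythe F*)
        grand = float(np.sum(n * m) / n.sum())
        num = float(np.sum(n * (m - grand) ** 2))
        ci = (1 - n / n.sum()) * sd**2
        den = float(np.sum(ci))
        f = num / den if den > 0 else (np.inf if num > 0 else 0.0)
        df2 = float(den**2 / np.sum(ci**2 / (n - 1)))
        df = (n.size - 1.0, df2)
        p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
        if f == 0.0:
            p = 1.0
    else:
        raise ValueError(f"unknown ANOVA method {method!r}")
    lev = bf = None
    if homogeneity:
        lev_res = stats.levene(*arrays, center="mean")
        bf_res = stats.levene(*arrays, center="median")
        lev = (float(lev_res.statistic), float(lev_res.pvalue))
        bf = (float(bf_res.statistic), float(bf_res.pvalue))
    return AnovaSummary(
        group_n=tuple(int(v) for v in n),
        group_mean=tuple(float(v) for v in m),
        group_sd=tuple(float(v) for v in sd),
        f=f,
        p=p,
        df=df,
        method=method,
        levene=lev,
        brown_forsythe=bf,
    )


def anova_from_summary(
    ns: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Classic one-way F from per-group (n, mean, SD) sufficient statistics."""
    n = np.asarray(ns, dtype=float)
    m = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if not (n.size == m.size == sd.size) or n.size < 2:
        raise ValueError("need matching n/mean/sd for at least two groups")
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sd <= 0):
        raise ValueError("group SDs must be positive")
    return _classic_f(n.astype(int), m, sd)


def bonferroni_posthoc(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """All pairwise t-tests on the pooled within-group MS, Bonferroni adjusted.

    Matches the usual post-hoc convention: t uses the pooled within-group
    mean square with N - k degrees of freedom; adjusted p = min(1, p * pairs).
    """
    arrays, n, m, sd = _group_stats(groups)
    k = n.size
    N = int(n.sum())
    ms_within = float(np.sum((n - 1) * sd**2) / (N - k))
    pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_within * (1.0 / n[i] + 1.0 / n[j]))
            if se == 0:
                t = 0.0 if m[i] == m[j] else np.inf
            else:
                t = (m[i] - m[j]) / se
            praw = float(2.0 * stats.t.sf(abs(t), N - k)) if np.isfinite(t) else 0.0
            rows.append(
                {
                    "pair": (i, j),
                    "mean_diff": float(m[i] - m[j]),
                    "t": float(t),
                    "p_raw": praw,
                    "p_adjusted": min(1.0, praw * pairs),
                }
            )
    return pd.DataFrame(rows)
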