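"""ROC evaluation of a continuous diagnostic marker.

Builds the empirical ROC curve with thresholds at midpoints between observed
scores (ties stepped simultaneously), the trapezoidal AUC — which equals the
tie-corrected Mann-Whitney probability estimate exactly — a normal-theory
confidence interval for the AUC (Hanley-McNeil variance by default, DeLong
optional), and the Youden-optimal cutoff J = sensitivity + specificity - 1.

Markers may indicate disease in either direction; by default the orientation
is chosen so the AUC is at least 0.5 and the chosen direction is reported
(``"higher"``: larger values indicate a case; ``"lower"``: smaller values do,
as for a down-regulated transcript).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RocResult", "roc_points", "auc", "auc_mannwhitney", "auc_ci", "youden_cutoff", "evaluate_marker"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    n_cases: int
    n_controls: int
    ci_method: str = "hanley-mcneil"
    degenerate: bool = False


def _validate(cases, controls):
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one case and one control score")
    return x, y


def _resolve_direction(x: np.ndarray, y: np.ndarray, direction: str) -> str:
    if direction in ("higher", "lower"):
        return direction
    if direction != "auto":
        raise ValueError(f"unknown direction {direction!r}")
    return "higher" if auc_mannwhitney(x, y, "higher") >= 0.5 else "lower"


def roc_points(cases, controls, direction: str = "higher") -> np.ndarray:
    """Empirical ROC curve as an array of (fpr, tpr, threshold) rows.

    Thresholds are midpoints between consecutive distinct pooled scores
    (with +/-inf at the ends); a subject is called positive when its oriented
    score exceeds the threshold.  Thresholds are reported in original units;
    under ``direction="lower"`` the positive call is "score below threshold".
    The curve runs from (0,0) to (1,1) and is monotone non-decreasing.
    """
    x, y = _validate(cases, controls)
    direction = _resolve_direction(x, y, direction)
    sign = 1.0 if direction == "higher" else -1.0
    xs, ys = sign * x, sign * y
    pooled = np.unique(np.r_[xs, ys])
    # thresholds descend from +inf so (fpr, tpr) ascends from (0,0) to (1,1)
    cuts = np.r_[np.inf, ((pooled[1:] + pooled[:-1]) / 2.0)[::-1], -np.inf]
    rows = []
    for t in cuts:
        tpr = float(np.mean(xs > t))
        fpr = float(np.mean(ys > t))
        rows.append((fpr, tpr, sign * t))
    return np.asarray(rows)


def auc(cases, controls, direction: str = "higher") -> float:
    """Trapezoidal area under the empirical ROC curve."""
    pts = roc_points(cases, controls, direction)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auc_mannwhitney(cases, controls, direction: str = "higher") -> float:
    """AUC as the Mann-Whitney probability (pairs won + half ties) / (n1*n0)."""
    x, y = _validate(cases, controls)
    sign = 1.0 if direction == "higher" else -1.0
    xs, ys = sign * x, sign * y
    pooled = np.r_[xs, ys]
    ranks = stats.rankdata(pooled)
    u = ranks[: xs.size].sum() - xs.size * (xs.size + 1) / 2.0
    return float(u / (xs.size * ys.size))


def _hanley_mcneil_var(a: float, n1: int, n0: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)


def _delong_var(x: np.ndarray, y: np.ndarray) -> float:
    # placement values: for each case, fraction of controls it beats (ties half)
    vx = np.array([np.mean((xi > y) + 0.5 * (xi == y)) for xi in x])
    vy = np.array([np.mean((x > yi) + 0.5 * (x == yi)) for yi in y])
    return float(np.var(vx, ddof=1) / x.size + np.var(vy, ddof=1) / y.size)


def auc_ci(
    auc_value: float,
    n_cases: int,
    n_controls: int,
    method: str = "hanley-mcneil",
    alpha: float = 0.05,
    scores_cases=None,
    scores_controls=None,
) -> tuple[float, float, float, bool]:
    """Normal-approximation CI for the AUC and two-sided p versus AUC = 0.5.

    Returns ``(lower, upper, p, degenerate)``; a degenerate AUC of exactly
    0 or 1 yields a CI truncated to [0, 1] with the flag set.  ``delong``
    requires the raw scores.
    """
    z = stats.norm.ppf(1 - alpha / 2.0)
    if method == "hanley-mcneil":
        var = _hanley_mcneil_var(auc_value, n_cases, n_controls)
    elif method == "delong":
        if scores_cases is None or scores_controls is None:
            raise ValueError("delong method requires the raw scores")
        x, y = _validate(scores_cases, scores_controls)
        var = _delong_var(1.0 * x, 1.0 * y)
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    degenerate = auc_value in (0.0, 1.0) or se == 0.0
    lower, upper = auc_value - z * se, auc_value + z * se
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(auc_value - 0.5) / se))
    else:
        p = 1.0 if auc_value == 0.5 else 0.0
    return max(lower, 0.0), min(upper, 1.0), p, degenerate


def youden_cutoff(points: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (lower false-positive rate).
    Returns ``(cutoff, sensitivity, specificity)``.
    """
    fpr, tpr = points[:, 0], points[:, 1]
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    k = best[np.argmin(fpr[best])]
    return float(points[k, 2]), float(tpr[k]), float(1.0 - fpr[k])


def evaluate_marker(
    cases,
    controls,
    direction: str = "auto",
    ci_method: str = "hanley-mcneil",
    alpha: float = 0.05,
) -> RocResult:
    """Full ROC evaluation: oriented AUC with CI and p, Youden cutoff."""
    x, y = _validate(cases, controls)
    direction = _resolve_direction(x, y, direction)
    pts = roc_points(x, y, direction)
    a = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    lower, upper, p, degenerate = auc_ci(
        a, x.size, y.size, method=ci_method, alpha=alpha,
        scores_cases=x, scores_controls=y,
    )
    cutoff, sens, spec = youden_cutoff(pts)
    return RocResult(
        auc=a,
        auc_ci=(lower, upper),
        auc_p=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        n_cases=x.size,
        n_controls=y.size,
        ci_method=ci_method,
        degenerate=degenerate,
    )
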