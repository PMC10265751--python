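"""Crossover analysis of additive interaction between two binary exposures.

A case-control cohort is crossed on a dichotomised biomarker (circRNA
expression above/below a cutoff) and a binary risk factor, giving four joint
exposure cells with the double-negative cell as reference.  Crude odds
ratios versus the reference carry Woolf (log-normal) confidence intervals.
Additive interaction is summarised by three measures on the odds-ratio
scale:

    RERI = OR11 - OR10 - OR01 + 1      (relative excess risk due to interaction)
    AP   = RERI / OR11                 (attributable proportion)
    S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (synergy index)

RERI = 0 (equivalently S = 1) means the joint effect is exactly the sum of
the single-exposure effects on the additive scale.  Confidence intervals use
the first-order delta method on the log-odds-ratio vector
beta = (ln OR10, ln OR01, ln OR11), whose covariance has diagonal equal to
the sum of reciprocal counts of the four cells defining each OR, and
off-diagonal 1/a_ref + 1/b_ref (shared reference cell) — identical to the
observed-information covariance of the saturated four-category logistic
model.  These intervals are symmetric about the point estimates on the
linear scale; a log-scale variant for S (the textbook construction) is
available behind a flag.

The significance rule follows standard epidemiological practice for this
design: additive interaction is declared only when the RERI interval
excludes 0 AND the S interval excludes 1; direction is synergistic for
S > 1, antagonistic for S < 1.

Critical value: the conventional two-decimal normal quantile (1.96 at
alpha = 0.05) is the default, matching the interval conventions of applied
crossover analyses; pass ``z`` explicitly for the exact quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roc import evaluate_marker

__all__ = [
    "CrossoverTable",
    "OddsRatioCI",
    "EstimateCI",
    "InteractionResult",
    "dichotomize",
    "build_crossover",
    "crude_or",
    "additive_interaction",
    "log_or_covariance",
    "interaction_cis",
    "classify_interaction",
    "analyze_crossover",
]

CELLS = ((0, 0), (1, 0), (0, 1), (1, 1))


def zcrit(alpha: float = 0.05, conventional: bool = True) -> float:
    """Normal critical value; two-decimal convention by default (1.96)."""
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return round(z, 2) if conventional else z


@dataclass(frozen=True)
class CrossoverTable:
    """2x2x2 counts: cells[(marker status, factor status)] = (cases, controls)."""

    marker: str
    factor: str
    cells: Mapping[tuple[int, int], tuple[int, int]]
    cutoff: str | float = "unspecified"

    def __post_init__(self) -> None:
        cells = {}
        for key in CELLS:
            if key not in self.cells:
                raise ValueError(f"missing crossover cell {key}")
            a, b = self.cells[key]
            if a < 0 or b < 0 or a != int(a) or b != int(b):
                raise ValueError(f"cell {key} counts must be non-negative integers")
            cells[key] = (int(a), int(b))
        object.__setattr__(self, "cells", cells)

    @property
    def n(self) -> int:
        return sum(a + b for a, b in self.cells.values())

    @property
    def estimable(self) -> bool:
        """True when every margin (each cell's case and control count) is positive."""
        return all(a > 0 and b > 0 for a, b in self.cells.values())

    def counts(self, correction: bool = False) -> dict[tuple[int, int], tuple[float, float]]:
        if correction:
            return {k: (a + 0.5, b + 0.5) for k, (a, b) in self.cells.items()}
        return {k: (float(a), float(b)) for k, (a, b) in self.cells.items()}


@dataclass(frozen=True)
class OddsRatioCI:
    value: float
    lower: float | None
    upper: float | None
    p: float | None


@dataclass(frozen=True)
class EstimateCI:
    value: float
    lower: float
    upper: float

    def excludes(self, null: float) -> bool:
        return not (self.lower <= null <= self.upper)


@dataclass(frozen=True)
class InteractionResult:
    table: CrossoverTable
    or10: OddsRatioCI
    or01: OddsRatioCI
    or11: OddsRatioCI
    reri: EstimateCI
    ap: EstimateCI
    s: EstimateCI | None
    significant_additive: bool
    direction: str  # "synergistic" | "antagonistic" | "none"
    alpha: float
    s_scale: str


def dichotomize(
    cohort: pd.DataFrame,
    marker: str,
    strategy: str = "youden",
    threshold: float | None = None,
    group_col: str = "group",
) -> tuple[pd.Series, float]:
    """Binary exposure status for a continuous marker: "+" iff value > threshold.

    strategies: ``youden`` (ROC-optimal cutoff from the case/control labels),
    ``median`` (pooled median), ``fixed`` (explicit ``threshold``).
    Returns ``(status, threshold)`` with status NaN where the marker is missing.
    """
    values = cohort[marker].astype(float)
    if strategy == "fixed":
        if threshold is None:
            raise ValueError("fixed strategy requires a threshold")
        cut = float(threshold)
    elif strategy == "median":
        cut = float(values.dropna().median())
    elif strategy == "youden":
        is_case = cohort[group_col] == "case"
        res = evaluate_marker(values[is_case], values[~is_case])
        cut = float(res.cutoff)
    else:
        raise ValueError(f"unknown dichotomization strategy {strategy!r}")
    status = pd.Series(np.where(values > cut, 1.0, 0.0), index=cohort.index)
    status[values.isna()] = np.nan
    return status, cut


def build_crossover(
    cohort: pd.DataFrame,
    marker: str,
    factor: str,
    strategy: str = "youden",
    threshold: float | None = None,
    group_col: str = "group",
) -> CrossoverTable:
    """Cross a dichotomised marker with a binary risk factor (complete cases)."""
    for col in (marker, factor, group_col):
        if col not in cohort.columns:
            raise KeyError(f"cohort lacks column {col!r}")
    status, cut = dichotomize(cohort, marker, strategy, threshold, group_col)
    df = pd.DataFrame(
        {
            "circ": status,
            "factor": cohort[factor].astype(float),
            "case": (cohort[group_col] == "case").astype(int),
        }
    ).dropna()
    cells = {}
    for ci, fi in CELLS:
        sub = df[(df["circ"] == ci) & (df["factor"] == fi)]
        cells[(ci, fi)] = (int(sub["case"].sum()), int((1 - sub["case"]).sum()))
    return CrossoverTable(marker=marker, factor=factor, cells=cells, cutoff=cut)


def crude_or(
    table: CrossoverTable,
    cell: tuple[int, int],
    alpha: float = 0.05,
    correction: bool = False,
    z: float | None = None,
) -> OddsRatioCI:
    """Crude OR of one joint-exposure cell versus the (0,0) reference cell.

    Woolf CI: exp(ln OR +/- z * sqrt(1/a + 1/b + 1/a_ref + 1/b_ref)); the
    Wald p tests OR = 1.  The reference cell itself returns OR 1 with no CI.
    Zero cells raise unless ``correction`` applies Haldane-Anscombe +0.5.
    """
    if cell not in CELLS:
        raise ValueError(f"unknown cell {cell}")
    if cell == (0, 0):
        return OddsRatioCI(1.0, None, None, None)
    counts = table.counts(correction)
    a, b = counts[cell]
    a0, b0 = counts[(0, 0)]
    if min(a, b, a0, b0) <= 0:
        raise ValueError(
            f"zero count in cell {cell} or reference; enable the continuity correction"
        )
    z = zcrit(alpha) if z is None else float(z)
    or_ = (a * b0) / (b * a0)
    se = math.sqrt(1 / a + 1 / b + 1 / a0 + 1 / b0)
    p = 2.0 * stats.norm.sf(abs(math.log(or_)) / se)
    return OddsRatioCI(
        value=or_,
        lower=math.exp(math.log(or_) - z * se),
        upper=math.exp(math.log(or_) + z * se),
        p=float(p),
    )


def additive_interaction(
    or10: float, or01: float, or11: float
) -> tuple[float, float, float | None]:
    """Point estimates (RERI, AP, S) from the three cell odds ratios.

    S is None (undefined, not an error) when its denominator
    (OR10 - 1) + (OR01 - 1) is zero.
    """
    for name, v in (("or10", or10), ("or01", or01), ("or11", or11)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11
    denom = (or10 - 1.0) + (or01 - 1.0)
    s = (or11 - 1.0) / denom if denom != 0.0 else None
    return reri, ap, s


def log_or_covariance(
    table: CrossoverTable, correction: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(beta, V): log cell ORs and their covariance.

    beta = (ln OR10, ln OR01, ln OR11).  V_kk is the sum of reciprocal
    counts of the four cells defining OR_k; V_kl = 1/a_ref + 1/b_ref for
    k != l because all three ORs share the reference cell.  Equals the
    observed-information covariance of the saturated four-category logistic
    fit.
    """
    counts = table.counts(correction)
    a0, b0 = counts[(0, 0)]
    if min(a0, b0) <= 0:
        raise ValueError("zero reference-cell count; enable the continuity correction")
    beta = np.empty(3)
    diag = np.empty(3)
    for k, cell in enumerate(((1, 0), (0, 1), (1, 1))):
        a, b = counts[cell]
        if min(a, b) <= 0:
            raise ValueError(f"zero count in cell {cell}; enable the continuity correction")
        beta[k] = math.log((a * b0) / (b * a0))
        diag[k] = 1 / a + 1 / b + 1 / a0 + 1 / b0
    off = 1 / a0 + 1 / b0
    V = np.full((3, 3), off)
    np.fill_diagonal(V, diag)
    return beta, V


def interaction_cis(
    table: CrossoverTable,
    alpha: float = 0.05,
    s_scale: str = "linear",
    correction: bool = False,
    z: float | None = None,
) -> InteractionResult:
    """Full additive-interaction analysis of a crossover table.

    Delta-method confidence intervals for RERI, AP and S (all symmetric about
    the point estimate on the linear scale).  ``s_scale="log"`` instead
    propagates the variance of ln S (the Hosmer-Lemeshow construction),
    which requires S > 0.
    """
    z = zcrit(alpha) if z is None else float(z)
    beta, V = log_or_covariance(table, correction)
    or10, or01, or11 = np.exp(beta)
    reri, ap, s = additive_interaction(or10, or01, or11)

    g_reri = np.array([-or10, -or01, or11])
    se_reri = float(np.sqrt(g_reri @ V @ g_reri))
    reri_ci = EstimateCI(reri, reri - z * se_reri, reri + z * se_reri)

    g_ap = np.array([-or10 / or11, -or01 / or11, (or10 + or01 - 1.0) / or11])
    se_ap = float(np.sqrt(g_ap @ V @ g_ap))
    ap_ci = EstimateCI(ap, ap - z * se_ap, ap + z * se_ap)

    s_ci: EstimateCI | None = None
    if s is not None:
        d = (or10 - 1.0) + (or01 - 1.0)
        g_s = np.array(
            [-(or11 - 1.0) * or10 / d**2, -(or11 - 1.0) * or01 / d**2, or11 / d]
        )
        se_s = float(np.sqrt(g_s @ V @ g_s))
        if s_scale == "linear":
            s_ci = EstimateCI(s, s - z * se_s, s + z * se_s)
        elif s_scale == "log":
            if s <= 0:
                raise ValueError("log-scale S interval requires S > 0")
            se_lns = se_s / s
            s_ci = EstimateCI(s, s * math.exp(-z * se_lns), s * math.exp(z * se_lns))
        else:
            raise ValueError(f"unknown s_scale {s_scale!r}")

    significant, direction = classify_interaction(reri_ci, s, s_ci)
    return InteractionResult(
        table=table,
        or10=crude_or(table, (1, 0), alpha, correction, z),
        or01=crude_or(table, (0, 1), alpha, correction, z),
        or11=crude_or(table, (1, 1), alpha, correction, z),
        reri=reri_ci,
        ap=ap_ci,
        s=s_ci,
        significant_additive=significant,
        direction=direction,
        alpha=alpha,
        s_scale=s_scale,
    )


def classify_interaction(
    reri_ci: EstimateCI,
    s: float | None,
    s_ci: EstimateCI | None,
) -> tuple[bool, str]:
    """Apply the additive-interaction significance rule.

    No additive interaction when the RERI interval contains 0 or the S
    interval contains 1; hence significance requires both RERI excluding 0
    and S excluding 1.  An undefined S yields "not significant".
    """
    if s is None or s_ci is None:
        return False, "none"
    significant = reri_ci.excludes(0.0) and s_ci.excludes(1.0)
    if not significant:
        return False, "none"
    return True, "synergistic" if s > 1.0 else "antagonistic"


def analyze_crossover(
    cohort: pd.DataFrame,
    marker: str,
    factor: str,
    strategy: str = "youden",
    threshold: float | None = None,
    alpha: float = 0.05,
    s_scale: str = "linear",
    correction: bool = False,
) -> InteractionResult:
    """Cohort-level convenience wrapper: dichotomise, cross, analyse."""
    table = build_crossover(cohort, marker, factor, strategy, threshold)
    if not table.estimable:
        raise ValueError(
            f"crossover table for {marker} x {factor} has an empty margin; "
            "odds ratios are not estimable"
        )
    return interaction_cis(table, alpha=alpha, s_scale=s_scale, correction=correction)
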