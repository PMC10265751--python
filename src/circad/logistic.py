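"""Logistic regression of disease status with odds ratios and Wald intervals.

Maximum likelihood is computed by iteratively reweighted least squares
(Newton scoring) with step halving, so the deviance is non-increasing across
iterations.  Wald intervals are exp(b +/- z * se).  Complete separation is
detected and flagged: coefficients diverge, so standard errors (and hence
ORs/CIs) are suppressed rather than reported as spuriously finite.

The model battery mirrors the covariate-adjustment sets used in the study
design this package targets: an unadjusted model per marker, a model
adjusted for demographics and classical risk factors, and a model further
adjusted for lipids and glucose-related covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticSpec",
    "LogisticFit",
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "fit_logistic",
    "fit_logistic_frame",
    "run_model_battery",
]

# adjustment sets: demographics + classical risk factors, then + lipids
MODEL1_COVARIATES = ("age", "sex_male", "bmi", "smoking", "drinking", "diabetes", "hypertension")
MODEL2_COVARIATES = MODEL1_COVARIATES + ("tc", "tg", "lpa", "ldl_c")


@dataclass(frozen=True)
class LogisticSpec:
    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    model_label: str = "custom"

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError(f"exposure {self.exposure!r} duplicated in covariates")

    @classmethod
    def univariate(cls, exposure: str, outcome: str = "group") -> "LogisticSpec":
        return cls(outcome, exposure, (), "univariate")

    @classmethod
    def model1(cls, exposure: str, outcome: str = "group") -> "LogisticSpec":
        return cls(outcome, exposure, MODEL1_COVARIATES, "model1")

    @classmethod
    def model2(cls, exposure: str, outcome: str = "group") -> "LogisticSpec":
        return cls(outcome, exposure, MODEL2_COVARIATES, "model2")


@dataclass
class LogisticFit:
    names: list[str]
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    deviance: float
    deviance_path: list[float]
    separation: bool
    n_obs: int

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2.0)
        with np.errstate(over="ignore"):
            or_ = np.exp(self.params)
            lo = np.exp(self.params - z * self.se)
            hi = np.exp(self.params + z * self.se)
        wald = np.where(self.se > 0, self.params / self.se, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(wald))
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "or": or_, "or_low": lo, "or_high": hi, "p": p},
            index=self.names,
        )


def fit_logistic(
    design: np.ndarray | pd.DataFrame,
    outcome: Sequence[float],
    weights: Sequence[float] | None = None,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS.

    ``outcome`` must be binary 0/1; ``weights`` are optional frequency
    weights (for grouped data).  Convergence is declared when the largest
    coefficient change falls below ``tol``.  Raises on rank deficiency.
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    def deviance(beta: np.ndarray) -> float:
        eta = X @ beta
        # log-likelihood via stable log(1 + exp(eta))
        return float(2.0 * np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

    beta = np.zeros(X.shape[1])
    dev = deviance(beta)
    path = [dev]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = w * mu * (1.0 - mu)
        # guard against exactly-saturated weights
        wt = np.maximum(wt, 1e-12)
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the deviance monotone non-increasing
        factor = 1.0
        new_beta = beta + step
        new_dev = deviance(new_beta)
        while new_dev > dev + 1e-12 and factor > 1e-8:
            factor /= 2.0
            new_beta = beta + factor * step
            new_dev = deviance(new_beta)
        delta = np.max(np.abs(new_beta - beta))
        beta, dev = new_beta, new_dev
        path.append(dev)
        if delta < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    # complete/quasi-complete separation: fitted probabilities at the data's
    # labels with diverging coefficients
    fitted_hard = np.all((mu > 1 - 1e-6) == (y == 1.0)) and np.all((mu < 1e-6) == (y == 0.0)) \
        and np.any((mu > 1 - 1e-6) | (mu < 1e-6))
    separation = (not converged and np.max(np.abs(beta)) > 15.0) or (
        fitted_hard and np.max(np.abs(beta)) > 15.0
    )
    wt = np.maximum(w * mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * wt[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if separation:
        se = np.full_like(se, np.nan)
        cov = np.full_like(cov, np.nan)
    return LogisticFit(
        names=names,
        params=beta,
        se=se,
        cov=cov,
        converged=converged and not separation,
        n_iter=n_iter,
        deviance=dev,
        deviance_path=path,
        separation=separation,
        n_obs=int(X.shape[0]),
    )


def fit_logistic_frame(
    cohort: pd.DataFrame, spec: LogisticSpec, case_label: str = "case"
) -> tuple[LogisticFit, int]:
    """Fit one spec on a cohort table with complete-case filtering.

    Returns ``(fit, n_complete)``.
    """
    cols = [spec.exposure, *spec.covariates]
    missing = [c for c in cols + [spec.outcome] if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks columns: {missing}")
    sub = cohort[[spec.outcome, *cols]].dropna()
    if sub.empty:
        raise ValueError("no complete cases for this model")
    y = (sub[spec.outcome] == case_label).astype(float) if sub[spec.outcome].dtype == object \
        else sub[spec.outcome].astype(float)
    fit = fit_logistic(sub[cols], y.to_numpy())
    return fit, len(sub)


def run_model_battery(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    specs: Sequence[LogisticSpec] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per marker and model: OR (Wald CI) and p for the marker term."""
    rows = []
    for marker in markers:
        model_specs = specs or [
            LogisticSpec.univariate(marker),
            LogisticSpec.model1(marker),
            LogisticSpec.model2(marker),
        ]
        for spec in model_specs:
            spec = LogisticSpec(spec.outcome, marker, spec.covariates, spec.model_label)
            fit, n_complete = fit_logistic_frame(cohort, spec)
            row = fit.summary(alpha).loc[marker]
            rows.append(
                {
                    "marker": marker,
                    "model": spec.model_label,
                    "n": n_complete,
                    "or": row["or"],
                    "or_low": row["or_low"],
                    "or_high": row["or_high"],
                    "p": row["p"],
                    "converged": fit.converged,
                    "separation": fit.separation,
                }
            )
    return pd.DataFrame(rows)
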