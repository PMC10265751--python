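"""Synthetic case-control cohort generation.

Generates subject-level cohorts with the statistical structure of a qPCR
validation study of circRNA biomarkers for coronary artery disease: a small
control arm against a much larger case arm, binary coronary risk factors
with group-specific prevalences, positively skewed relative-expression
values, and clinical covariates.  Relative expression is modelled per group
as log-normal — the conventional positive-skew model for 2^-ddCt data —
with parameters moment-matched on the log scale to a published median and
interquartile range: mu = ln(median), sigma = ln(q3/q1) / (2 * z_0.75).

A separate generator plants a known additive-scale interaction: two binary
exposures A and B drawn from marginal prevalences, and disease drawn from
logit p = b0 + ba*A + bb*B + bab*A*B.  Because the crossover cells condition
on the other exposure, the crude cell odds ratios equal exp(ba), exp(bb) and
exp(ba+bb+bab), so the implied population RERI is
exp(ba+bb+bab) - exp(ba) - exp(bb) + 1; downstream estimators can be checked
against it.

Randomness: one integer seed feeds an independent, name-keyed stream per
variable (seed plus a stable hash of the variable name), so adding a new
variable to a config never perturbs the values drawn for existing ones.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import CtRecord

__all__ = [
    "ConfigurationError",
    "RiskFactorSpec",
    "ExpressionSpec",
    "CovariateSpec",
    "EffectModel",
    "CohortConfig",
    "Subject",
    "lognormal_params_from_quartiles",
    "default_cohort_config",
    "generate_cohort",
    "generate_interaction_cohort",
    "generate_ct_records",
    "subjects_from_frame",
]

_Z75 = 0.6744897501960817  # standard normal upper quartile


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
    return p


def lognormal_params_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartiles.

    Matching is exact on the log scale: the log of a log-normal is normal,
    so mu = ln(median) and sigma = ln(q3/q1) / (2 * z_0.75).
    """
    if not (0 < q1 <= median <= q3):
        raise ConfigurationError(f"need 0 < q1 <= median <= q3, got {(q1, median, q3)}")
    if q1 == q3:
        raise ConfigurationError("degenerate interquartile range (q1 == q3)")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class RiskFactorSpec:
    name: str
    prevalence_cases: float
    prevalence_controls: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(f"{self.name} prevalence_cases", self.prevalence_cases)
        _check_prob(f"{self.name} prevalence_controls", self.prevalence_controls)
        _check_prob(f"{self.name} missing_rate", self.missing_rate)


@dataclass(frozen=True)
class ExpressionSpec:
    """Per-group log-normal expression model for one circRNA.

    ``median_*`` and ``(q1, q3)`` quartiles are in relative-expression units
    (fold, dimensionless); the log-scale location/scale are derived by
    quartile matching.
    """

    name: str
    median_cases: float
    iqr_cases: tuple[float, float]
    median_controls: float
    iqr_controls: tuple[float, float]
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.log_params("case")
        self.log_params("control")
        _check_prob(f"{self.name} missing_rate", self.missing_rate)

    def log_params(self, group: str) -> tuple[float, float]:
        if group == "case":
            return lognormal_params_from_quartiles(self.median_cases, *self.iqr_cases)
        if group == "control":
            return lognormal_params_from_quartiles(self.median_controls, *self.iqr_controls)
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """A clinical covariate drawn independently per group.

    families: ``normal`` (mean, sd), ``lognormal`` (median, q1, q3),
    ``halfnormal`` (sigma; for non-negative scores piled near zero),
    ``binary`` (probability of 1).  ``family_controls`` overrides the family
    for the control arm when its shape differs qualitatively (e.g. a severity
    score that is log-normal in cases but piled at zero in controls).
    """

    name: str
    family: str
    params_cases: tuple[float, ...]
    params_controls: tuple[float, ...]
    missing_rate: float = 0.0
    family_controls: str | None = None

    _FAMILIES = ("normal", "lognormal", "halfnormal", "binary")

    def _family_for(self, group: str) -> str:
        return self.family_controls if (group == "control" and self.family_controls) else self.family

    def __post_init__(self) -> None:
        for fam in (self.family, self.family_controls or self.family):
            if fam not in self._FAMILIES:
                raise ConfigurationError(f"unknown covariate family {fam!r}")
        for label, group, params in (
            ("cases", "case", self.params_cases),
            ("controls", "control", self.params_controls),
        ):
            fam = self._family_for(group)
            if fam == "normal" and (len(params) != 2 or params[1] <= 0):
                raise ConfigurationError(f"{self.name} {label}: normal needs (mean, sd>0)")
            if fam == "lognormal":
                lognormal_params_from_quartiles(params[0], params[1], params[2])
            if fam == "halfnormal" and (len(params) != 1 or params[0] <= 0):
                raise ConfigurationError(f"{self.name} {label}: halfnormal needs (sigma>0,)")
            if fam == "binary":
                _check_prob(f"{self.name} {label}", params[0])
        _check_prob(f"{self.name} missing_rate", self.missing_rate)

    def draw(self, rng: np.random.Generator, group: str, n: int) -> np.ndarray:
        params = self.params_cases if group == "case" else self.params_controls
        fam = self._family_for(group)
        if fam == "normal":
            return rng.normal(params[0], params[1], size=n)
        if fam == "lognormal":
            mu, sigma = lognormal_params_from_quartiles(*params)
            return rng.lognormal(mu, sigma, size=n)
        if fam == "halfnormal":
            return np.abs(rng.normal(0.0, params[0], size=n))
        return (rng.random(n) < params[0]).astype(float)


@dataclass(frozen=True)
class EffectModel:
    """Logistic generative model for a planted two-exposure interaction."""

    intercept: float
    log_or_a: float
    log_or_b: float
    log_or_ab: float
    prevalence_a: float
    prevalence_b: float

    def __post_init__(self) -> None:
        _check_prob("prevalence_a", self.prevalence_a)
        _check_prob("prevalence_b", self.prevalence_b)

    def implied_reri(self) -> float:
        """Population RERI implied by the cell odds ratios of the model."""
        return (
            math.exp(self.log_or_a + self.log_or_b + self.log_or_ab)
            - math.exp(self.log_or_a)
            - math.exp(self.log_or_b)
            + 1.0
        )


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int
    n_controls: int
    risk_factors: tuple[RiskFactorSpec, ...] = ()
    expression: tuple[ExpressionSpec, ...] = ()
    covariates: tuple[CovariateSpec, ...] = ()
    effect_model: EffectModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        object.__setattr__(self, "risk_factors", tuple(self.risk_factors))
        object.__setattr__(self, "expression", tuple(self.expression))
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class Subject:
    """One participant: disease label, risk factors, covariates, expression."""

    id: str
    group: str
    risk_factors: Mapping[str, float]
    covariates: Mapping[str, float]
    expression: Mapping[str, float]
    gensini: float | None = None


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator stream keyed by (seed, variable name)."""
    key = int.from_bytes(hashlib.blake2b(name.encode(), digest_size=8).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _mask_missing(rng: np.random.Generator, values: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        values = values.astype(float).copy()
        values[rng.random(values.shape[0]) < rate] = np.nan
    return values


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort; one row per subject, cases first.

    Deterministic given ``config.seed``; each variable has its own stream.
    """
    n = config.n_cases + config.n_controls
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    is_case = group == "case"
    out = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "group": group,
        }
    )
    for spec in config.risk_factors:
        rng = _stream(config.seed, f"risk:{spec.name}")
        p = np.where(is_case, spec.prevalence_cases, spec.prevalence_controls)
        vals = (rng.random(n) < p).astype(float)
        out[spec.name] = _mask_missing(rng, vals, spec.missing_rate)
    for spec in config.covariates:
        rng = _stream(config.seed, f"cov:{spec.name}")
        vals = np.empty(n)
        vals[is_case] = spec.draw(rng, "case", int(is_case.sum()))
        vals[~is_case] = spec.draw(rng, "control", int((~is_case).sum()))
        out[spec.name] = _mask_missing(rng, vals, spec.missing_rate)
    for spec in config.expression:
        rng = _stream(config.seed, f"expr:{spec.name}")
        mu_ca, sd_ca = spec.log_params("case")
        mu_co, sd_co = spec.log_params("control")
        vals = np.empty(n)
        vals[is_case] = rng.lognormal(mu_ca, sd_ca, int(is_case.sum()))
        vals[~is_case] = rng.lognormal(mu_co, sd_co, int((~is_case).sum()))
        out[spec.name] = _mask_missing(rng, vals, spec.missing_rate)
    return out


def generate_interaction_cohort(
    config: CohortConfig, exposure_a: str = "A", exposure_b: str = "B"
) -> pd.DataFrame:
    """Cohort with a planted logistic interaction between two binary exposures.

    ``n_cases + n_controls`` subjects are drawn from the population model
    (the realised case count is random); exposures use group-free marginal
    prevalences and the disease label follows the logistic effect model.
    """
    model = config.effect_model
    if model is None:
        raise ConfigurationError("generate_interaction_cohort requires an effect_model")
    n = config.n_cases + config.n_controls
    rng_a = _stream(config.seed, f"exposure:{exposure_a}")
    rng_b = _stream(config.seed, f"exposure:{exposure_b}")
    rng_y = _stream(config.seed, "outcome")
    a = (rng_a.random(n) < model.prevalence_a).astype(float)
    b = (rng_b.random(n) < model.prevalence_b).astype(float)
    logit = model.intercept + model.log_or_a * a + model.log_or_b * b + model.log_or_ab * a * b
    p = 1.0 / (1.0 + np.exp(-logit))
    y = rng_y.random(n) < p
    return pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "group": np.where(y, "case", "control"),
            exposure_a: a,
            exposure_b: b,
        }
    )


def generate_ct_records(
    cohort: pd.DataFrame,
    marker: str,
    calibrator_id: str | None = None,
    reference_ct: float = 18.0,
    base_delta_ct: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[CtRecord], float]:
    """Invert the 2^-ddCt transform into synthetic triplicate Ct records.

    Each subject's dCt is ``base_delta_ct - log2(expression)``, so quantifying
    the records with calibrator dCt = ``base_delta_ct`` (the returned value)
    recovers the expression exactly when ``noise_sd`` is zero.  With
    ``calibrator_id`` set, the returned calibrator dCt is that subject's own
    dCt, and quantification recovers expression *relative to that subject*.

    Returns ``(records, calibrator_delta_ct)``.
    """
    if marker not in cohort.columns:
        raise KeyError(f"marker {marker!r} not in cohort")
    rng = _stream(seed, f"ct:{marker}")
    sub = cohort.loc[cohort[marker].notna(), ["id", marker]]
    if calibrator_id is not None:
        match = sub.loc[sub["id"] == calibrator_id, marker]
        if match.empty:
            raise KeyError(f"calibrator subject {calibrator_id!r} has no expression value")
        cal_dct = base_delta_ct - math.log2(float(match.iloc[0]))
    else:
        cal_dct = base_delta_ct
    records = []
    for sid, expr in zip(sub["id"], sub[marker]):
        dct = base_delta_ct - math.log2(float(expr))
        ref = np.full(3, reference_ct)
        tgt = np.full(3, reference_ct + dct)
        if noise_sd > 0:
            ref = ref + rng.normal(0.0, noise_sd, 3)
            tgt = tgt + rng.normal(0.0, noise_sd, 3)
        records.append(
            CtRecord(
                subject_id=str(sid),
                target=marker,
                ct_target=tuple(np.maximum(tgt, 0.0)),
                ct_reference=tuple(np.maximum(ref, 0.0)),
            )
        )
    return records, cal_dct


def subjects_from_frame(
    cohort: pd.DataFrame,
    risk_factors: Sequence[str] = (),
    covariates: Sequence[str] = (),
    expression: Sequence[str] = (),
) -> list[Subject]:
    """Row-wise view of a cohort table as :class:`Subject` records."""
    def _clean(row, names):
        return {k: (None if pd.isna(row[k]) else float(row[k])) for k in names}

    subjects = []
    for _, row in cohort.iterrows():
        subjects.append(
            Subject(
                id=str(row["id"]),
                group=str(row["group"]),
                risk_factors=_clean(row, risk_factors),
                covariates=_clean(row, covariates),
                expression=_clean(row, expression),
                gensini=(None if "gensini" not in cohort.columns or pd.isna(row["gensini"])
                         else float(row["gensini"])),
            )
        )
    return subjects


def default_cohort_config(seed: int = 0, missing_rate: float = 0.0) -> CohortConfig:
    """Default configuration emulating the published validation cohort.

    256 cases / 49 controls; risk-factor prevalences, expression medians and
    IQRs, and covariate summaries taken from the published baseline table.
    ``missing_rate`` applies MCAR missingness to risk factors and expression,
    emulating the incomplete exposure data evident in the published
    crossover-cell totals.
    """
    risk_factors = (
        RiskFactorSpec("smoking", 0.413, 0.356, missing_rate),
        RiskFactorSpec("drinking", 0.289, 0.178, missing_rate),
        RiskFactorSpec("hypertension", 0.630, 0.489, missing_rate),
        RiskFactorSpec("diabetes", 0.204, 0.111, missing_rate),
    )
    expression = (
        ExpressionSpec("hsa_circRPRD1A", 0.466, (0.215, 0.728), 0.613, (0.490, 1.465), missing_rate),
        ExpressionSpec("hsa_circHERPUD2", 0.722, (0.402, 1.633), 0.976, (0.765, 1.448), missing_rate),
        ExpressionSpec("hsa_circLMBR1", 1.520, (0.582, 4.384), 1.286, (0.569, 4.746), missing_rate),
        ExpressionSpec("hsa_circDHTKD1", 1.318, (0.711, 3.988), 1.062, (0.570, 1.513), missing_rate),
    )
    covariates = (
        CovariateSpec("sex_male", "binary", (189 / 256,), (23 / 49,)),
        CovariateSpec("age", "normal", (66.0, 11.7), (65.0, 13.0)),
        CovariateSpec("bmi", "normal", (25.028, 3.512), (24.988, 3.599)),
        CovariateSpec("sbp", "normal", (130.317, 17.282), (131.867, 18.910)),
        CovariateSpec("tc", "lognormal", (3.605, 3.065, 4.373), (4.075, 3.125, 4.665)),
        CovariateSpec("tg", "lognormal", (1.270, 0.948, 1.713), (1.205, 0.880, 1.635)),
        CovariateSpec("hdl_c", "lognormal", (0.980, 0.860, 1.135), (1.085, 0.886, 1.286)),
        CovariateSpec("ldl_c", "lognormal", (2.110, 1.728, 2.705), (2.230, 1.766, 2.843)),
        CovariateSpec("glu", "lognormal", (5.035, 4.518, 5.853), (4.980, 4.486, 5.650)),
        CovariateSpec("lpa", "lognormal", (172.0, 84.0, 382.0), (131.5, 61.75, 320.0)),
        # severity score: strongly right-skewed in cases, piled at zero in
        # controls (published control upper quartile 4.5 -> halfnormal sigma
        # with q75 at 4.5: 4.5 / 1.1503 = 3.912)
        CovariateSpec("gensini", "lognormal", (48.0, 24.0, 93.75), (3.912,),
                      family_controls="halfnormal"),
    )
    config = CohortConfig(
        n_cases=256,
        n_controls=49,
        risk_factors=risk_factors,
        expression=expression,
        covariates=covariates,
        seed=seed,
    )
    return config
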