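"""End-to-end orchestration: simulate/ingest -> describe -> ROC -> logistic
-> severity ANOVA -> crossover interaction, with paper-style table rendering.

The pipeline is deterministic given the configuration seed; per-marker
failures are collected rather than aborting other markers, and a provenance
block (config hash, seed, package version) accompanies every report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .anova import anova_oneway, bonferroni_posthoc, quartile_groups, QUARTILE_LABELS
from .cohort import CohortConfig, default_cohort_config, generate_cohort
from .descriptives import describe_cohort
from .interaction import InteractionResult, analyze_crossover
from .logistic import run_model_battery
from .roc import evaluate_marker

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "render_table7", "render_interaction"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort_path: str | None = None  # None -> simulate the default synthetic cohort
    markers: tuple[str, ...] = ("hsa_circRPRD1A", "hsa_circHERPUD2")
    factors: tuple[str, ...] = ("smoking", "drinking", "hypertension")
    describe_variables: tuple[str, ...] = ()
    dichotomize_strategy: str = "youden"
    severity_col: str = "gensini"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    descriptives: pd.DataFrame
    roc: pd.DataFrame
    logistic: pd.DataFrame
    anova: pd.DataFrame
    interactions: list[InteractionResult]
    provenance: dict
    errors: dict[str, str] = field(default_factory=dict)


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.cohort_path is None:
        return generate_cohort(default_cohort_config(seed=config.seed))
    sep = "," if config.cohort_path.endswith(".csv") else "\t"
    return pd.read_csv(config.cohort_path, sep=sep)


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> AnalysisReport:
    """Run every analysis stage on a cohort table (simulated when absent)."""
    if cohort is None:
        cohort = _load_cohort(config)
    missing = [c for c in (*config.markers, *config.factors, "group") if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing required columns: {missing}")
    errors: dict[str, str] = {}
    is_case = cohort["group"] == "case"

    describe_vars = list(config.describe_variables) or [
        c for c in cohort.columns if c not in ("id", "group")
    ]
    descriptives = describe_cohort(cohort, describe_vars)

    roc_rows = []
    for marker in config.markers:
        try:
            res = evaluate_marker(cohort.loc[is_case, marker], cohort.loc[~is_case, marker],
                                  alpha=config.alpha)
            roc_rows.append(
                {
                    "marker": marker, "auc": res.auc, "auc_low": res.auc_ci[0],
                    "auc_high": res.auc_ci[1], "p": res.auc_p, "cutoff": res.cutoff,
                    "sensitivity": res.sensitivity, "specificity": res.specificity,
                    "direction": res.direction,
                }
            )
        except Exception as exc:  # noqa: BLE001 - collected per marker
            errors[f"roc:{marker}"] = str(exc)
    roc_table = pd.DataFrame(roc_rows)

    try:
        logistic_table = run_model_battery(cohort, config.markers, alpha=config.alpha)
    except Exception as exc:  # noqa: BLE001
        errors["logistic"] = str(exc)
        logistic_table = pd.DataFrame()

    anova_rows = []
    if config.severity_col in cohort.columns:
        strata = quartile_groups(cohort[config.severity_col])
        for marker in config.markers:
            try:
                groups = [
                    cohort.loc[(strata.labels == lab).to_numpy(), marker].dropna()
                    for lab in QUARTILE_LABELS
                ]
                summary = anova_oneway(groups)
                posthoc = bonferroni_posthoc(groups)
                anova_rows.append(
                    {
                        "marker": marker,
                        "f": summary.f,
                        "p": summary.p,
                        "levene_p": summary.levene[1],
                        "brown_forsythe_p": summary.brown_forsythe[1],
                        "min_adjusted_p": posthoc["p_adjusted"].min(),
                    }
                )
            except Exception as exc:  # noqa: BLE001
                errors[f"anova:{marker}"] = str(exc)
    anova_table = pd.DataFrame(anova_rows)

    interactions: list[InteractionResult] = []
    for marker in config.markers:
        for factor in config.factors:
            try:
                interactions.append(
                    analyze_crossover(
                        cohort, marker, factor,
                        strategy=config.dichotomize_strategy, alpha=config.alpha,
                    )
                )
            except Exception as exc:  # noqa: BLE001
                errors[f"interaction:{marker}x{factor}"] = str(exc)

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "n_subjects": int(len(cohort)),
        "n_cases": int(is_case.sum()),
    }
    return AnalysisReport(
        descriptives=descriptives,
        roc=roc_table,
        logistic=logistic_table,
        anova=anova_table,
        interactions=interactions,
        provenance=provenance,
        errors=errors,
    )


def _fmt_or(o) -> tuple[str, str]:
    if o.lower is None:
        return "1.000", ""
    return f"{o.value:.3f}", f"({o.lower:.3f}-{o.upper:.3f})"


def render_interaction(result: InteractionResult) -> pd.DataFrame:
    """One crossover panel in the published layout: four count rows then the
    S / AP / RERI lines with confidence intervals."""
    t = result.table
    rows = []
    labels = {(0, 0): "--", (1, 0): "+-", (0, 1): "-+", (1, 1): "++"}
    ors = {(0, 0): None, (1, 0): result.or10, (0, 1): result.or01, (1, 1): result.or11}
    for cell in ((0, 0), (1, 0), (0, 1), (1, 1)):
        a, b = t.cells[cell]
        o = ors[cell]
        if o is None:
            or_s, ci_s, p_s = "1.000", "", ""
        else:
            or_s, ci_s = _fmt_or(o)
            p_s = f"{o.p:.3f}"
        rows.append({"row": labels[cell], "cases": a, "controls": b,
                     "OR": or_s, "95% CI": ci_s, "p": p_s})
    def measure_row(name, est):
        if est is None:
            return {"row": name, "cases": "", "controls": "", "OR": "NA",
                    "95% CI": "undefined (zero denominator)", "p": ""}
        return {"row": name, "cases": "", "controls": "",
                "OR": f"{est.value:.3f}", "95% CI": f"({est.lower:.3f}-{est.upper:.3f})", "p": ""}
    rows.append(measure_row("S", result.s))
    rows.append(measure_row("AP", result.ap))
    rows.append(measure_row("RERI", result.reri))
    out = pd.DataFrame(rows)
    out.attrs["marker"] = t.marker
    out.attrs["factor"] = t.factor
    out.attrs["classification"] = (
        result.direction if result.significant_additive else "not significant"
    )
    return out


def render_table7(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Stack crossover panels into one delimited table."""
    if not results:
        raise ValueError("no interaction results to render")
    frames = []
    for res in results:
        panel = render_interaction(res)
        panel.insert(0, "marker", res.table.marker)
        panel.insert(1, "factor", res.table.factor)
        frames.append(panel)
    return pd.concat(frames, ignore_index=True)
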