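"""Tests for the synthetic case-control cohort generator."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from circad.cohort import (
    CohortConfig,
    ConfigurationError,
    EffectModel,
    ExpressionSpec,
    RiskFactorSpec,
    default_cohort_config,
    generate_cohort,
    generate_ct_records,
    generate_interaction_cohort,
    lognormal_params_from_quartiles,
)
from circad.interaction import CrossoverTable, interaction_cis
from circad.quant import relative_expression


def test_default_cohort_shape_and_determinism():
    cfg = default_cohort_config(seed=7)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert len(a) == 305
    assert (a["group"] == "case").sum() == 256
    assert a.to_csv() == b.to_csv()  # byte-identical serialisation
    c = generate_cohort(default_cohort_config(seed=8))
    assert a.to_csv() != c.to_csv()


def test_adding_variable_does_not_perturb_existing_streams():
    cfg = default_cohort_config(seed=3)
    extended = dataclasses.replace(
        cfg, risk_factors=cfg.risk_factors + (RiskFactorSpec("extra", 0.5, 0.5),)
    )
    a = generate_cohort(cfg)
    b = generate_cohort(extended)
    for col in a.columns:
        assert (a[col] == b[col]).all()


def test_degenerate_prevalence_zero_cases_smoke():
    cfg = CohortConfig(
        n_cases=200, n_controls=50,
        risk_factors=(RiskFactorSpec("smoking", 0.0, 0.5),), seed=1,
    )
    cohort = generate_cohort(cfg)
    assert cohort.loc[cohort.group == "case", "smoking"].sum() == 0


def test_invalid_prevalence_rejected():
    with pytest.raises(ConfigurationError):
        RiskFactorSpec("smoking", 1.2, 0.3)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_cases=0, n_controls=5)


def test_marginal_prevalence_calibration():
    """Empirical prevalence within 3 binomial SEs of the target at n=10,000/group."""
    cfg = dataclasses.replace(default_cohort_config(seed=11), n_cases=10_000, n_controls=10_000)
    cohort = generate_cohort(cfg)
    is_case = cohort.group == "case"
    for spec in cfg.risk_factors:
        for grp, p in ((is_case, spec.prevalence_cases), (~is_case, spec.prevalence_controls)):
            phat = cohort.loc[grp, spec.name].mean()
            tol = 3 * math.sqrt(p * (1 - p) / 10_000)
            assert abs(phat - p) < tol, spec.name


def test_expression_quartiles_match_published_summaries():
    """Log-normal matching reproduces the configured median and quartile ratio.

    A log-normal is symmetric on the log scale, so it matches the published
    median and the IQR ratio q3/q1 exactly; the individual quartiles need not
    coincide when the published quartiles are log-asymmetric.
    """
    cfg = dataclasses.replace(default_cohort_config(seed=5), n_cases=40_000, n_controls=40_000)
    cohort = generate_cohort(cfg)
    vals = cohort.loc[cohort.group == "case", "hsa_circRPRD1A"]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    assert med == pytest.approx(0.466, rel=0.05)
    assert q3 / q1 == pytest.approx(0.728 / 0.215, rel=0.05)


def test_lognormal_quartile_matching_closed_form():
    mu, sigma = lognormal_params_from_quartiles(1.0, 0.5, 2.0)
    assert mu == pytest.approx(0.0)
    z75 = stats.norm.ppf(0.75)
    assert math.exp(mu + z75 * sigma) == pytest.approx(2.0)
    assert math.exp(mu - z75 * sigma) == pytest.approx(0.5)


def test_null_expression_two_group_p_uniform():
    """Identical case/control expression: Wilcoxon p over seeds ~ Uniform(0,1)."""
    spec = ExpressionSpec("m", 1.0, (0.6, 1.7), 1.0, (0.6, 1.7))
    pvals = []
    for seed in range(120):
        cfg = CohortConfig(n_cases=120, n_controls=120, expression=(spec,), seed=seed)
        cohort = generate_cohort(cfg)
        x = cohort.loc[cohort.group == "case", "m"]
        y = cohort.loc[cohort.group == "control", "m"]
        pvals.append(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestInteractionCohort:
    def test_requires_effect_model(self):
        with pytest.raises(ConfigurationError):
            generate_interaction_cohort(CohortConfig(n_cases=10, n_controls=10))

    @pytest.mark.parametrize(
        "ba, bb, bab, expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (math.log(2), math.log(2), 0.0, 1.0),  # 4 - 2 - 2 + 1
        ],
    )
    def test_implied_reri_closed_form(self, ba, bb, bab, expected):
        model = EffectModel(-1.0, ba, bb, bab, 0.4, 0.3)
        assert model.implied_reri() == pytest.approx(expected)

    def test_reri_recovery_large_n(self):
        """Estimated RERI from the simulated 2x2x2 table within 3 SEs of truth."""
        model = EffectModel(-0.6, math.log(2), math.log(1.5), math.log(1.4), 0.4, 0.3)
        cfg = CohortConfig(n_cases=10_000, n_controls=10_000, effect_model=model, seed=42)
        cohort = generate_interaction_cohort(cfg, "A", "B")
        cells = {}
        for a in (0, 1):
            for b in (0, 1):
                sub = cohort[(cohort.A == a) & (cohort.B == b)]
                cells[(a, b)] = (int((sub.group == "case").sum()), int((sub.group == "control").sum()))
        table = CrossoverTable("A", "B", cells)
        res = interaction_cis(table)
        se = (res.reri.upper - res.reri.lower) / (2 * 1.96)
        assert abs(res.reri.value - model.implied_reri()) < 3 * se


class TestCtRecords:
    def test_zero_noise_round_trip(self):
        cfg = default_cohort_config(seed=2)
        cohort = generate_cohort(cfg).head(30)
        records, cal_dct = generate_ct_records(cohort, "hsa_circRPRD1A")
        recovered = {r.subject_id: relative_expression(r, cal_dct).value for r in records}
        for _, row in cohort.iterrows():
            assert recovered[row["id"]] == pytest.approx(row["hsa_circRPRD1A"], rel=1e-12)

    def test_named_calibrator_self_reference(self):
        cfg = default_cohort_config(seed=2)
        cohort = generate_cohort(cfg).head(10)
        cal_id = cohort["id"].iloc[0]
        records, cal_dct = generate_ct_records(cohort, "hsa_circRPRD1A", calibrator_id=cal_id)
        rec = next(r for r in records if r.subject_id == cal_id)
        res = relative_expression(rec, cal_dct)
        assert res.delta_delta_ct == pytest.approx(0.0)
        assert res.value == pytest.approx(1.0)

    def test_unknown_calibrator_rejected(self):
        cohort = generate_cohort(default_cohort_config(seed=2)).head(5)
        with pytest.raises(KeyError):
            generate_ct_records(cohort, "hsa_circRPRD1A", calibrator_id="ghost")

    def test_noisy_ct_unbiased_in_log_domain(self):
        """Ct noise of 0.1 cycles leaves log-expression recovery unbiased."""
        cfg = dataclasses.replace(default_cohort_config(seed=9), n_cases=1000, n_controls=1000)
        cohort = generate_cohort(cfg)
        records, cal_dct = generate_ct_records(cohort, "hsa_circHERPUD2", noise_sd=0.1, seed=9)
        errors = []
        truth = dict(zip(cohort["id"], cohort["hsa_circHERPUD2"]))
        for r in records:
            v = relative_expression(r, cal_dct).value
            errors.append(math.log(v) - math.log(truth[r.subject_id]))
        assert abs(np.mean(errors)) < 3 * np.std(errors) / math.sqrt(len(errors)) + 1e-3
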