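"""Tests for the crossover additive-interaction analysis (RERI / AP / S)."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circad.cohort import CohortConfig, EffectModel, generate_interaction_cohort
from circad.interaction import (
    CrossoverTable,
    EstimateCI,
    additive_interaction,
    analyze_crossover,
    build_crossover,
    classify_interaction,
    crude_or,
    dichotomize,
    interaction_cis,
    log_or_covariance,
)
from circad.logistic import fit_logistic
from circad.published import TABLE_CROSSOVER
from circad.roc import evaluate_marker

RPRD1A_SMOKING = TABLE_CROSSOVER[("hsa_circRPRD1A", "smoking")]


def make_table(cells):
    return CrossoverTable("m", "f", cells)


class TestDichotomize:
    @pytest.fixture
    def cohort(self, rng):
        n = 120
        group = np.r_[["case"] * 80, ["control"] * 40]
        expr = np.r_[rng.lognormal(-0.6, 0.8, 80), rng.lognormal(-0.2, 0.8, 40)]
        return pd.DataFrame({"group": group, "m": expr})

    def test_fixed_threshold(self):
        df = pd.DataFrame({"group": ["case", "control"], "m": [0.5, 1.5]})
        status, cut = dichotomize(df, "m", "fixed", threshold=1.0)
        assert list(status) == [0.0, 1.0] and cut == 1.0

    def test_median_splits_in_half(self, rng):
        vals = rng.permutation(np.arange(1.0, 41.0))
        df = pd.DataFrame({"group": ["case"] * 40, "m": vals})
        status, _ = dichotomize(df, "m", "median")
        assert status.sum() == 20

    def test_youden_threshold_matches_roc_module(self, cohort):
        _, cut = dichotomize(cohort, "m", "youden")
        is_case = cohort.group == "case"
        roc = evaluate_marker(cohort.loc[is_case, "m"], cohort.loc[~is_case, "m"])
        assert cut == roc.cutoff

    def test_unknown_strategy_rejected(self, cohort):
        with pytest.raises(ValueError):
            dichotomize(cohort, "m", "tertile")


class TestBuildCrossover:
    def test_one_subject_per_cell(self):
        rows = []
        for circ in (0.5, 1.5):
            for fac in (0.0, 1.0):
                rows.append({"group": "case", "m": circ, "f": fac})
                rows.append({"group": "control", "m": circ, "f": fac})
        table = build_crossover(pd.DataFrame(rows), "m", "f", strategy="fixed", threshold=1.0)
        assert all(table.cells[c] == (1, 1) for c in table.cells)

    def test_missing_factor_excluded(self):
        df = pd.DataFrame(
            {"group": ["case"] * 4 + ["control"] * 4,
             "m": [0.5, 0.5, 1.5, 1.5] * 2,
             "f": [0, 1, 0, np.nan, 0, 1, np.nan, 1]}
        )
        table = build_crossover(df, "m", "f", strategy="fixed", threshold=1.0)
        assert table.n == 6

    def test_generated_cohort_marginals(self):
        model = EffectModel(-0.5, 0.3, 0.2, 0.1, 0.4, 0.3)
        cfg = CohortConfig(n_cases=5000, n_controls=5000, effect_model=model, seed=5)
        cohort = generate_interaction_cohort(cfg, "A", "B")
        cohort["Acont"] = cohort["A"] + 0.5  # continuous stand-in, threshold at 1
        table = build_crossover(cohort, "Acont", "B", strategy="fixed", threshold=1.0)
        frac_a = sum(a + b for (ci, fi), (a, b) in table.cells.items() if ci == 1) / table.n
        assert frac_a == pytest.approx(0.4, abs=3 * math.sqrt(0.4 * 0.6 / 10000))


class TestCrudeOr:
    def test_published_joint_cells(self):
        o = crude_or(RPRD1A_SMOKING, (1, 1))
        assert o.value == pytest.approx(58 / 325)
        assert round(o.value, 3) == 0.178
        assert (round(o.lower, 3), round(o.upper, 3)) == (0.033, 0.974)
        assert round(o.p, 3) == 0.047

        o2 = crude_or(TABLE_CROSSOVER[("hsa_circHERPUD2", "drinking")], (1, 1))
        assert o2.value == pytest.approx(58 / 198)
        assert (round(o2.lower, 3), round(o2.upper, 3)) == (0.046, 1.848)

    def test_reference_cell_or_one_no_ci(self):
        o = crude_or(RPRD1A_SMOKING, (0, 0))
        assert o.value == 1.0 and o.lower is None

    def test_zero_cell_needs_correction(self):
        t = make_table({(0, 0): (5, 0), (1, 0): (3, 2), (0, 1): (4, 2), (1, 1): (2, 2)})
        with pytest.raises(ValueError):
            crude_or(t, (1, 1))
        o = crude_or(t, (1, 1), correction=True)
        assert o.value == pytest.approx((2.5 * 0.5) / (2.5 * 5.5))


class TestAdditiveInteraction:
    def test_null_ors_reri_zero_s_undefined(self):
        reri, ap, s = additive_interaction(1.0, 1.0, 1.0)
        assert reri == 0.0 and ap == 0.0 and s is None

    def test_exact_additivity(self):
        # or11 = or10 + or01 - 1 -> RERI = AP = 0, S = 1
        reri, ap, s = additive_interaction(2.0, 3.0, 4.0)
        assert reri == pytest.approx(0.0, abs=1e-15)
        assert ap == pytest.approx(0.0, abs=1e-15)
        assert s == pytest.approx(1.0)

    def test_multiplicativity_is_not_additivity(self):
        # multiplicative null or11 = or10*or01 still has positive RERI
        reri, _, _ = additive_interaction(2.0, 2.0, 4.0)
        assert reri == pytest.approx(1.0)

    def test_published_smoking_panel_fractions(self):
        reri, ap, s = additive_interaction(86 / 715, 82 / 130, 58 / 325)
        assert round(reri, 3) == 0.427
        assert round(ap, 3) == 2.395
        assert round(s, 3) == 0.658

    def test_published_drinking_panel_fractions(self):
        reri, ap, s = additive_interaction(164 / 1122, 58 / 132, 58 / 198)
        assert round(reri, 3) == 0.707
        assert round(s, 3) == 0.500

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            additive_interaction(0.0, 1.0, 1.0)

    @given(
        st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10)
    )
    def test_single_exposure_swap_invariance(self, a, b, c):
        """RERI and S are symmetric in the two single-exposure odds ratios."""
        r1, _, s1 = additive_interaction(a, b, c)
        r2, _, s2 = additive_interaction(b, a, c)
        assert r1 == pytest.approx(r2, rel=1e-12)
        # S blows up near a zero denominator; compare only when well-defined
        if s1 is not None and s2 is not None and abs((a - 1) + (b - 1)) > 1e-6:
            assert s1 == pytest.approx(s2, rel=1e-9)


class TestCovariance:
    def test_off_diagonal_is_reference_reciprocals(self):
        _, V = log_or_covariance(RPRD1A_SMOKING)
        assert V[0, 1] == pytest.approx(1 / 65 + 1 / 2)
        assert V[0, 0] == pytest.approx(1 / 43 + 1 / 11 + 1 / 65 + 1 / 2)

    def test_matches_saturated_logistic_observed_information(self):
        """V equals the coefficient covariance of the saturated 4-category fit."""
        t = RPRD1A_SMOKING
        rows, ys, ws = [], [], []
        for (ci, fi), (a, b) in t.cells.items():
            for y, w in ((1.0, a), (0.0, b)):
                rows.append([ci, fi, ci * fi])
                ys.append(y)
                ws.append(w)
        fit = fit_logistic(np.array(rows, dtype=float), np.array(ys), weights=np.array(ws))
        # beta order: (bA, bB, bAB); our V is for (bA, bB, bA+bB+bAB)
        L = np.array([[1.0, 0, 0], [0, 1, 0], [1, 1, 1]])
        cov = fit.cov[1:, 1:]
        beta, V = log_or_covariance(t)
        assert np.allclose(L @ fit.params[1:], beta, atol=1e-6)
        assert np.allclose(L @ cov @ L.T, V, atol=1e-6)


class TestInteractionCIs:
    def test_cis_symmetric_about_estimates(self):
        for table in TABLE_CROSSOVER.values():
            res = interaction_cis(table)
            for est in (res.reri, res.ap, res.s):
                assert est.upper - est.value == pytest.approx(est.value - est.lower, rel=1e-9)

    def test_count_inflation_shrinks_cis(self):
        t = RPRD1A_SMOKING
        big = make_table({k: (a * 100, b * 100) for k, (a, b) in t.cells.items()})
        small_res, big_res = interaction_cis(t), interaction_cis(big)
        assert big_res.reri.value == pytest.approx(small_res.reri.value, rel=1e-9)
        ratio = (big_res.reri.upper - big_res.reri.lower) / (
            small_res.reri.upper - small_res.reri.lower
        )
        assert ratio == pytest.approx(0.1, rel=0.01)  # O(1/sqrt(scale))

    def test_s_undefined_reported_not_raised(self):
        # or10 = or01 = 1 exactly: equal case/control odds in single-exposure cells
        t = make_table({(0, 0): (10, 10), (1, 0): (10, 10), (0, 1): (10, 10), (1, 1): (30, 10)})
        res = interaction_cis(t)
        assert res.s is None
        assert not res.significant_additive

    def test_log_scale_s_variant(self):
        res = interaction_cis(RPRD1A_SMOKING, s_scale="log")
        assert res.s.lower > 0  # log-scale interval is positive by construction
        assert res.s.value == pytest.approx(interaction_cis(RPRD1A_SMOKING).s.value)


class TestClassification:
    def test_published_drinking_intervals_antagonistic(self):
        sig, direction = classify_interaction(
            EstimateCI(0.707, 0.315, 1.099), 0.500, EstimateCI(0.500, 0.218, 0.782)
        )
        assert sig and direction == "antagonistic"

    def test_reri_interval_containing_zero_not_significant(self):
        sig, direction = classify_interaction(
            EstimateCI(0.428, -1.210, 2.065), 0.658, EstimateCI(0.658, -0.727, 2.042)
        )
        assert not sig and direction == "none"

    def test_synergistic_rule_application(self):
        sig, direction = classify_interaction(
            EstimateCI(0.3, 0.1, 0.5), 2.0, EstimateCI(2.0, 1.2, 3.0)
        )
        assert sig and direction == "synergistic"

    def test_undefined_s_not_significant(self):
        sig, direction = classify_interaction(EstimateCI(0.5, 0.2, 0.8), None, None)
        assert not sig and direction == "none"


class TestAnalyzeCrossover:
    def test_cohort_level_pipeline(self, rng):
        n = 400
        group = np.r_[["case"] * 250, ["control"] * 150]
        expr = np.r_[rng.lognormal(-0.5, 0.7, 250), rng.lognormal(0.0, 0.7, 150)]
        factor = (rng.random(n) < 0.4).astype(float)
        df = pd.DataFrame({"group": group, "m": expr, "f": factor})
        res = analyze_crossover(df, "m", "f", strategy="median")
        assert res.table.n == n
        assert res.reri.value == pytest.approx(
            res.or11.value - res.or10.value - res.or01.value + 1.0
        )
        assert res.ap.value == pytest.approx(res.reri.value / res.or11.value)
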