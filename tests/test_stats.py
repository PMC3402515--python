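"""Reporting odds ratio, logistic fits, change-in-estimate selection, baseline tests.

Frozen expected values were computed directly from the closed forms:
ad/(bc), Woolf se = sqrt(1/a+1/b+1/c+1/d), and the 2x2 chi-square
n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casenoncase import (ContingencyTable, StatsError, baseline_test,
                         change_in_estimate_select, fit_logistic, ror_2x2)
from casenoncase.stats import SingularityError, round_half_up


def expand_table(a, b, c, d, **extra):
    """Individual-level rows for a 2x2 table (the saturated logistic design)."""
    rows = ([{"is_case": True, "exposed": True}] * a
            + [{"is_case": True, "exposed": False}] * b
            + [{"is_case": False, "exposed": True}] * c
            + [{"is_case": False, "exposed": False}] * d)
    df = pd.DataFrame(rows)
    for k, v in extra.items():
        df[k] = v
    return df


class TestRor2x2:
    def test_worked_example_margins(self):
        res = ror_2x2(ContingencyTable(96, 231, 47, 1588))
        assert res.estimate == pytest.approx(14.041448, abs=1e-5)
        assert res.se_log == pytest.approx(0.1914471, abs=1e-6)
        assert res.ci_low == pytest.approx(9.648323, abs=1e-5)
        assert res.ci_high == pytest.approx(20.434874, abs=1e-5)
        assert res.p_value < 1e-10

    def test_equal_exposure_odds_gives_unity(self):
        res = ror_2x2(ContingencyTable(10, 90, 50, 450))
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_requires_correction(self):
        with pytest.raises(StatsError):
            ror_2x2(ContingencyTable(5, 0, 3, 7), zero_correction=False)

    def test_haldane_anscombe_correction(self):
        res = ror_2x2(ContingencyTable(5, 0, 3, 7), zero_correction=True)
        assert res.estimate == pytest.approx((5.5 * 7.5) / (0.5 * 3.5), abs=1e-9)

    def test_invalid_cells_rejected(self):
        with pytest.raises(StatsError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(StatsError):
            ContingencyTable(0, 0, 3, 4)


cells = st.integers(1, 400)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_ror_symmetry_and_ci_log_symmetry(a, b, c, d):
    r1 = ror_2x2(ContingencyTable(a, b, c, d))
    r2 = ror_2x2(ContingencyTable(c, d, a, b))
    assert r1.estimate * r2.estimate == pytest.approx(1.0, rel=1e-9)
    assert (math.log(r1.ci_high) - r1.log_beta) == pytest.approx(
        r1.log_beta - math.log(r1.ci_low), abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
def test_ror_strictly_increases_in_exposed_cases(a, b, c, d):
    lo = ror_2x2(ContingencyTable(a, b, c, d)).estimate
    hi = ror_2x2(ContingencyTable(a + 1, b, c, d)).estimate
    assert hi > lo


class TestFitLogistic:
    def test_saturated_2x2_equals_closed_form(self):
        rows = expand_table(96, 231, 47, 1588)
        fit = fit_logistic(rows, ["exposed"])
        assert fit.converged
        assert fit.coefficients["exposed"] == pytest.approx(
            math.log(96 * 1588 / (231 * 47)), abs=1e-6)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(a=st.integers(2, 40), b=st.integers(2, 40), c=st.integers(2, 40),
           d=st.integers(2, 40))
    def test_closed_form_equivalence_property(self, a, b, c, d):
        fit = fit_logistic(expand_table(a, b, c, d), ["exposed"])
        assert fit.coefficients["exposed"] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-6)

    def test_constant_outcome_rejected(self):
        rows = pd.DataFrame({"is_case": [True] * 10, "exposed": [True, False] * 5})
        with pytest.raises(StatsError, match="variation"):
            fit_logistic(rows, ["exposed"])

    def test_aliased_terms_named(self):
        rows = expand_table(10, 10, 10, 10)
        rows["copy"] = rows["exposed"]
        with pytest.raises(SingularityError) as err:
            fit_logistic(rows, ["exposed", "copy"])
        assert "copy" in err.value.aliased or "exposed" in err.value.aliased

    def test_monte_carlo_recovery_of_unit_log_odds(self):
        rng = np.random.default_rng(2024)
        n = 20_000
        x = rng.random(n) < 0.4
        p = 1 / (1 + np.exp(-(-1.0 + 1.0 * x)))
        y = rng.random(n) < p
        fit = fit_logistic(pd.DataFrame({"is_case": y, "exposed": x}), ["exposed"])
        beta, se = fit.coefficients["exposed"], fit.standard_errors["exposed"]
        assert abs(beta - 1.0) < 3 * se

    def test_separation_sets_warning_flag(self):
        rows = expand_table(20, 0, 0, 20)
        fit = fit_logistic(rows, ["exposed"])
        assert fit.separation_warning


def _confounded_rows(n=10_000, gamma_exposure=math.log(4), gamma_outcome=math.log(3),
                     seed=11):
    """Outcome-conditional draw with one binary confounder of prevalence 0.3."""
    rng = np.random.default_rng(seed)
    is_case = np.arange(n) < n // 6
    p_conf = np.where(is_case, 0.3 * 3 / (0.7 + 0.3 * 3), 0.3)  # odds x gamma_outcome
    conf = rng.random(n) < p_conf
    logit = -4.5 + math.log(8) * is_case + gamma_exposure * conf
    exposed = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame({"is_case": is_case, "exposed": exposed, "confounder": conf,
                         "noise": rng.random(n) < 0.5})


class TestChangeInEstimate:
    def test_orthogonal_candidate_not_selected(self):
        rows = _confounded_rows()
        selected, crude, adjusted = change_in_estimate_select(
            rows, candidates=["noise"], threshold=0.10)
        assert selected == []
        assert adjusted.coefficients["exposed"] == pytest.approx(
            crude.coefficients["exposed"], abs=1e-9)

    def test_strong_confounder_selected(self):
        rows = _confounded_rows()
        selected, crude, adjusted = change_in_estimate_select(
            rows, candidates=["confounder", "noise"], threshold=0.10)
        assert selected == ["confounder"]
        # adjusting moves the estimate towards the conditional effect
        assert adjusted.coefficients["exposed"] != crude.coefficients["exposed"]

    def test_threshold_monotone_on_fixed_data(self):
        rows = _confounded_rows(gamma_exposure=math.log(1.9), gamma_outcome=math.log(1.6))
        _, crude, _ = change_in_estimate_select(rows, candidates=[], threshold=0.10)
        fit_with = fit_logistic(rows, ["exposed", "confounder"])
        change = abs(fit_with.coefficients["exposed"] - crude.coefficients["exposed"]) \
            / abs(crude.coefficients["exposed"])
        assert 0.0 < change < 1.0
        below, _, _ = change_in_estimate_select(rows, ["confounder"], threshold=change * 0.9)
        above, _, _ = change_in_estimate_select(rows, ["confounder"], threshold=min(change * 1.1, 1.0))
        assert below == ["confounder"]
        assert above == []

    def test_zero_threshold_selects_all_converging_candidates(self):
        rows = _confounded_rows()
        selected, _, _ = change_in_estimate_select(
            rows, candidates=["confounder", "noise"], threshold=1e-12)
        assert selected == ["confounder", "noise"]

    def test_forced_candidate_overlap_rejected(self):
        rows = _confounded_rows()
        with pytest.raises(StatsError):
            change_in_estimate_select(rows, ["confounder"], forced=["confounder"])


class TestBaselineTest:
    def test_identical_groups_p_one(self):
        flags = np.array([True] * 30 + [False] * 70)
        name, _, p = baseline_test(flags, flags.copy(), "categorical")
        assert p == pytest.approx(1.0)

    def test_antidepressant_chi_square_statistic(self):
        cases = np.array([True] * 4 + [False] * 323)
        noncases = np.array([True] * 74 + [False] * 1561)
        name, stat, p = baseline_test(cases, noncases, "categorical")
        assert name == "chi_square"
        assert stat == pytest.approx(7.786477, abs=1e-5)

    def test_small_expected_cell_switches_to_fisher(self):
        cases = np.array([True] * 1 + [False] * 9)
        noncases = np.array([True] * 0 + [False] * 90)
        name, _, _ = baseline_test(cases, noncases, "categorical")
        assert name == "fisher_exact"

    def test_continuous_uses_welch_t(self):
        rng = np.random.default_rng(5)
        name, _, p = baseline_test(rng.normal(0, 1, 100), rng.normal(1, 2, 100), "continuous")
        assert name == "welch_t"
        assert p < 0.01

    def test_multilevel_categorical_rejected(self):
        with pytest.raises(StatsError):
            baseline_test(np.array([0, 1, 2]), np.array([0, 1]), "categorical")


@pytest.mark.parametrize("x,expected", [(29.35, 29.4), (2.85, 2.9), (31.25, 31.3), (2.0, 2.0)])
def test_round_half_up_matches_table_convention(x, expected):
    assert round_half_up(x, 1) == expected
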