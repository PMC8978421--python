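"""Standardized distances, aggregation rules, and the R-indicator."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rddframes as rf
from rddframes.synthetic import MarginTable


def _distance_oracle(p_a: Fraction, p_b: Fraction) -> float:
    """Eq.-independent recomputation with exact rational arithmetic."""
    num = Fraction(100) * (p_b - p_a)
    denom_sq = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2
    return float(num) / math.sqrt(float(denom_sq))


def test_distance_hand_value():
    d = rf.standardized_distance(0.5, 0.6)
    assert d == pytest.approx(100 * 0.1 / math.sqrt((0.25 + 0.24) / 2))
    assert d == pytest.approx(20.2030509, abs=1e-6)


def test_distance_identity_and_degenerate_cases():
    assert rf.standardized_distance(0.3, 0.3) == 0.0
    assert rf.standardized_distance(0.0, 0.0) == 0.0
    assert rf.standardized_distance(1.0, 1.0) == 0.0
    with pytest.raises(rf.DataError):
        rf.standardized_distance(0.0, 1.0)
    with pytest.raises(rf.DataError):
        rf.standardized_distance(-0.1, 0.5)


def test_distance_matches_rational_oracle_on_grid():
    grid = [Fraction(k, 20) for k in range(21)]
    for p_a in grid:
        for p_b in grid:
            if {p_a, p_b} <= {Fraction(0), Fraction(1)} and p_a != p_b:
                continue
            d = rf.standardized_distance(float(p_a), float(p_b))
            if p_a == p_b:
                assert d == 0.0
            else:
                assert d == pytest.approx(_distance_oracle(p_a, p_b), rel=1e-12)
                assert d == -rf.standardized_distance(float(p_b), float(p_a))
                assert (d > 0) == (p_b > p_a)


@settings(deadline=None, max_examples=200)
@given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
def test_distance_antisymmetry_property(p_a, p_b):
    d = rf.standardized_distance(p_a, p_b)
    assert d == pytest.approx(-rf.standardized_distance(p_b, p_a), abs=1e-9)
    assert (d == 0.0) == (p_a == p_b)


def test_aggregation_is_two_level_unweighted_mean():
    # category sizes never weight the aggregation
    assert rf.variable_distance([-2.0, 4.0, 6.0]) == pytest.approx(4.0)
    assert rf.mean_distance([2.0, 4.0]) == pytest.approx(3.0)


def test_balance_report_zero_when_margins_match():
    cats = pd.DataFrame({"g": ["a", "b", "a", "b"]})
    margins = [MarginTable("g", ("a", "b"), (0.5, 0.5))]
    rep = rf.balance_report(cats, np.ones(4), margins)
    assert rep.mean_d == 0.0
    assert (rep.categories["d"] == 0).all()


def test_balance_report_two_category_variable_reports_both():
    cats = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 4})
    margins = [MarginTable("g", ("a", "b"), (0.5, 0.5))]
    rep = rf.balance_report(cats, np.ones(10), margins)
    d = rep.categories.set_index("category")["d"]
    assert d["a"] == pytest.approx(-d["b"])
    assert rep.variable_d["g"] == pytest.approx(abs(d["a"]))


def test_balance_report_unknown_category_raises():
    cats = pd.DataFrame({"g": ["a", "z"]})
    margins = [MarginTable("g", ("a", "b"), (0.5, 0.5))]
    with pytest.raises(rf.DataError, match="z"):
        rf.balance_report(cats, np.ones(2), margins)


def test_balance_scale_invariance(survey, margins, sample_design):
    respondents, _ = survey
    ws = rf.df_weights(respondents, sample_design)
    rep1 = rf.balance_report(respondents, ws.weights, margins)
    rep2 = rf.balance_report(respondents, 7.3 * ws.weights, margins)
    assert rep1.mean_d == pytest.approx(rep2.mean_d, rel=1e-12)


# ---------------------------------------------------------------------------
# R-indicator
# ---------------------------------------------------------------------------


def _two_stratum_case(rate_a: float, rate_b: float, n_pop: int = 4000, seed=0):
    rng = np.random.default_rng(seed)
    bench = pd.DataFrame({"stratum": ["a"] * (n_pop // 2) + ["b"] * (n_pop // 2)})
    take_a = int(round(rate_a * n_pop / 2))
    take_b = int(round(rate_b * n_pop / 2))
    sample = pd.DataFrame({"stratum": ["a"] * take_a + ["b"] * take_b})
    return sample, bench


def test_r_indicator_two_stratum_closed_form():
    """Saturated binary-covariate fit reproduces 1 - 2*SD of the known rates."""
    sample, bench = _two_stratum_case(0.3, 0.1)
    res = rf.r_indicator(sample, None, bench, ["stratum"])
    # propensities {0.3, 0.1} at population shares (0.5, 0.5): SD = 0.1
    assert res.r == pytest.approx(1 - 2 * 0.1, abs=1e-3)
    assert res.propensity_sd == pytest.approx(0.1, abs=5e-4)


def test_r_indicator_homogeneous_sample_near_one():
    sample, bench = _two_stratum_case(0.2, 0.2)
    res = rf.r_indicator(sample, None, bench, ["stratum"])
    assert res.r > 0.995


def test_r_indicator_monotone_in_heterogeneity():
    """Wider stratum sampling-rate ratios strictly decrease R."""
    rs = []
    for rate_a in (0.2, 0.3, 0.4):
        sample, bench = _two_stratum_case(rate_a, 0.1)
        rs.append(rf.r_indicator(sample, None, bench, ["stratum"]).r)
    assert rs[0] > rs[1] > rs[2]


def test_r_indicator_weight_scale_invariance(survey, population, sample_design):
    respondents, _ = survey
    persons, _ = population
    ws = rf.df_weights(respondents, sample_design)
    r1 = rf.r_indicator(respondents, ws.weights, persons, ["sex", "age_band"])
    r2 = rf.r_indicator(respondents, 100.0 * ws.weights, persons,
                        ["sex", "age_band"])
    assert r1.r == pytest.approx(r2.r, abs=1e-10)


def test_r_indicator_bounds_on_fitted_scenario(fitted):
    for label, res in fitted.r_indicators.items():
        assert 0.0 <= res.r <= 1.0, label
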