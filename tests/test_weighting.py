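"""Design-weight formulas, counterfactual SF construction, dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rddframes as rf


def design(n_ll=1, N_ll=1000, n_cell=2, N_cell=1000):
    return rf.SampleDesign(n_ll, N_ll, n_cell, N_cell)


def test_df_probability_hand_arithmetic():
    # f_ll = 0.001, t_ll/e_ll = 1/2; f_cell = 0.002, t_c = 1
    pi = rf.df_selection_probability(1, 2, 1, 1, design())
    assert pi == pytest.approx(0.0005 + 0.002)
    assert 1 / pi == pytest.approx(400.0)


def test_df_probability_cell_only_drops_landline_term():
    pi = rf.df_selection_probability(0, 1, 1, 1, design())
    assert pi == pytest.approx(0.002)


def test_df_probability_linear_in_multiplicity():
    pi1 = rf.df_selection_probability(0, 1, 1, 1, design())
    pi2 = rf.df_selection_probability(0, 1, 2, 1, design())
    assert pi2 == pytest.approx(2 * pi1)


def test_sf_probability_and_dominance():
    d = rf.SampleDesign(100, 10_000, 100, 10_000)
    assert rf.sf_selection_probability(1, d) == pytest.approx(0.01)
    assert rf.sf_selection_probability(2, d) == pytest.approx(0.02)
    # for a both-equipped respondent the SF probability drops the landline term
    pi_df = rf.df_selection_probability(1, 2, 1, 1, d)
    assert rf.sf_selection_probability(1, d) <= pi_df


def test_probability_above_one_raises():
    d = rf.SampleDesign(900, 1000, 900, 1000)
    with pytest.raises(rf.DataError):
        rf.df_selection_probability(3, 1, 3, 1, d, cap=3)


def test_inconsistent_household_data_raises():
    with pytest.raises(rf.DataError):
        rf.df_selection_probability(1, 0, 1, 1, design())


def test_multiplicity_cap_truncates():
    pi_capped = rf.df_selection_probability(0, 1, 9, 1, design(), cap=3)
    pi_three = rf.df_selection_probability(0, 1, 3, 1, design())
    assert pi_capped == pytest.approx(pi_three)


def test_doubling_frame_and_sample_leaves_pi_unchanged():
    d1 = design(10, 1000, 20, 2000)
    d2 = design(20, 2000, 40, 4000)
    for t_ll, e_ll, t_c in [(0, 1, 1), (1, 2, 1), (2, 4, 2)]:
        assert rf.df_selection_probability(t_ll, e_ll, t_c, 1, d1) == pytest.approx(
            rf.df_selection_probability(t_ll, e_ll, t_c, 1, d2))


def test_counterfactual_sf_is_cell_subset(toy_respondents):
    d = design()
    sf, ws = rf.build_counterfactual_sf(toy_respondents, d)
    assert (sf["frame"] == "cell").all()
    assert len(sf) == 3
    assert (ws.weights > 0).all() and np.isfinite(ws.weights).all()
    with pytest.raises(rf.DataError):
        rf.build_counterfactual_sf(
            toy_respondents[toy_respondents.frame == "landline"], d)


def test_weight_dispersion_hand_values():
    ratio, cv = rf.weight_dispersion([1.0, 2.0, 3.0])
    assert ratio == pytest.approx(3.0)
    # population SD: mean 2, var 2/3
    assert cv == pytest.approx(np.sqrt(2 / 3) / 2)
    ratio, cv = rf.weight_dispersion([5.0, 5.0, 5.0])
    assert ratio == 1.0 and cv == 0.0
    with pytest.raises(rf.DataError):
        rf.weight_dispersion([1.0, 0.0])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0.01, 1e3), min_size=2, max_size=30),
       st.floats(0.01, 100.0))
def test_dispersion_scale_invariance(weights, c):
    r1, cv1 = rf.weight_dispersion(weights)
    r2, cv2 = rf.weight_dispersion([c * w for w in weights])
    assert r1 == pytest.approx(r2, rel=1e-9)
    assert cv1 == pytest.approx(cv2, rel=1e-6, abs=1e-12)


def test_sf_weights_less_dispersed_than_df(fitted):
    """One-stage cell design: lower weight CV than the dual-frame design."""
    assert fitted.design_weights["SF"].cv < fitted.design_weights["DF"].cv
    assert fitted.calibrated["SF"].cv < fitted.calibrated["DF"].cv


def test_horvitz_thompson_recovers_covered_population_sizes(population, frames):
    """Design-weighted respondent totals estimate the covered population sizes.

    Full response, small sampling fractions; 60 fieldwork replicates give a
    Monte-Carlo check that the DF estimator targets the any-phone population
    and the SF estimator the cell-owning population.
    """
    persons, _ = population
    everyone = persons.copy()
    for col in ("contact_cell", "contact_ll", "coop"):
        everyone[col] = 1.0
    cfg0 = rf.FieldworkConfig(n_landline=400, n_cell=600, partial_prob=0.0,
                              other_prob=0.0, handoff_prob=1.0,
                              max_call_attempts=5)
    design = rf.SampleDesign(400, frames.N_ll, 600, frames.N_cell)
    n_covered = int(((persons.n_cell > 0) | (persons.n_landline > 0)).sum())
    n_cell_owned = int((persons.n_cell > 0).sum())

    df_totals, sf_totals = [], []
    for seed in range(60):
        resp, _ = rf.simulate_calls(frames, everyone, cfg0.with_seed(seed))
        ws = rf.df_weights(resp, design)
        df_totals.append(ws.weights.sum())
        _, ws_sf = rf.build_counterfactual_sf(resp, design)
        sf_totals.append(ws_sf.weights.sum())
    for totals, target in ((df_totals, n_covered), (sf_totals, n_cell_owned)):
        mean = np.mean(totals)
        mc_se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(mean - target) < 4 * mc_se, (mean, target, mc_se)
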