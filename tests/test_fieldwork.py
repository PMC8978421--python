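"""Fieldwork simulation: number draws, Kish selection, dispositions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rddframes as rf
from rddframes.fieldwork import DISPOSITION_CODES
from rddframes.synthetic import AGE_BANDS


def test_draw_numbers_deterministic_and_exhaustive(frames):
    cfg = rf.FieldworkConfig(n_landline=100, n_cell=frames.N_cell, seed=3)
    ll1, c1 = rf.draw_numbers(frames, cfg)
    ll2, c2 = rf.draw_numbers(frames, cfg)
    assert np.array_equal(ll1, ll2) and np.array_equal(c1, c2)
    assert len(set(ll1)) == 100
    assert np.array_equal(np.sort(c1), np.arange(frames.N_cell))


def test_draw_numbers_rejects_oversized_sample(frames):
    cfg = rf.FieldworkConfig(n_landline=frames.N_ll + 1, n_cell=10)
    with pytest.raises(rf.ConfigError):
        rf.draw_numbers(frames, cfg)


def test_draw_inclusion_probability_is_n_over_N(frames):
    """Each number's inclusion frequency over many draws approximates n/N."""
    n, N = 200, frames.N_ll
    hits = np.zeros(N)
    reps = 400
    for seed in range(reps):
        cfg = rf.FieldworkConfig(n_landline=n, n_cell=10, seed=seed)
        ll, _ = rf.draw_numbers(frames, cfg)
        hits[ll] += 1
    # pooled check: total inclusions are Binomial(reps*N, n/N) in expectation
    p = n / N
    freq = hits.mean() / reps
    se = np.sqrt(p * (1 - p) / (reps * N))
    assert abs(freq - p) < 4 * se


@pytest.mark.parametrize("size", [2, 3])
def test_kish_selection_is_uniform(size):
    """Selection shares match 1/e within exact binomial bounds, 10k trials."""
    rng = np.random.default_rng(42)
    members = list(range(size))
    n_trials = 10_000
    counts = np.zeros(size)
    for _ in range(n_trials):
        counts[rf.kish_select(members, rng)] += 1
    lo, hi = stats.binom.interval(1 - 1e-4, n_trials, 1 / size)
    assert np.all(counts >= lo) and np.all(counts <= hi)


def test_kish_single_member_certain():
    rng = np.random.default_rng(0)
    assert rf.kish_select(["only"], rng) == "only"
    with pytest.raises(rf.DataError):
        rf.kish_select([], rng)


def test_dispositions_partition_dialed_numbers(survey, field_config):
    _, disp = survey
    by_frame = disp.groupby("frame")["count"].sum()
    assert by_frame["landline"] == field_config.n_landline
    assert by_frame["cell"] == field_config.n_cell
    assert (disp["count"] >= 0).all()
    assert set(disp["code"]) == set(DISPOSITION_CODES)


def test_respondents_exist_and_own_origin_numbers(survey, population):
    respondents, _ = survey
    persons, _ = population
    merged = respondents.merge(persons[["person_id", "n_cell", "n_landline"]],
                               on="person_id", how="left")
    assert merged["n_cell"].notna().all()
    cell = merged.loc[merged["frame"] == "cell"]
    assert (cell["n_cell"] >= 1).all()
    ll = merged.loc[merged["frame"] == "landline"]
    assert (ll["n_landline"] >= 1).all()
    # multiplicity of the origin frame is at least 1 and e_cell is fixed at 1
    assert (cell["t_cell"] >= 1).all() and (ll["t_ll"] >= 1).all()
    assert (respondents["e_cell"] == 1).all()


def test_full_cooperation_interviews_every_working_cell_number(population):
    persons, households = population
    frames = rf.build_frames(persons, households, nonworking_rate_ll=0.0,
                             nonworking_rate_cell=0.0)
    everyone = persons.copy()
    everyone["contact_cell"] = 1.0
    everyone["contact_ll"] = 1.0
    everyone["coop"] = 1.0
    cfg = rf.FieldworkConfig(n_landline=0, n_cell=500, partial_prob=0.0,
                             other_prob=0.0, seed=1)
    resp, disp = rf.simulate_calls(frames, everyone, cfg)
    assert disp.set_index(["frame", "code"]).loc[("cell", "I"), "count"] == 500
    assert len(resp) == 500


def test_zero_contact_yields_no_interviews(population, frames):
    persons, _ = population
    nobody = persons.copy()
    nobody["contact_cell"] = 0.0
    nobody["contact_ll"] = 0.0
    cfg = rf.FieldworkConfig(n_landline=300, n_cell=300, seed=1)
    resp, disp = rf.simulate_calls(frames, nobody, cfg)
    assert resp.empty
    d = disp.set_index(["frame", "code"])["count"]
    assert d[("cell", "I")] == 0 and d[("landline", "I")] == 0


def test_landline_needs_more_numbers_per_complete(survey, field_config):
    """Two-stage route + more non-working numbers: landline dials/complete higher."""
    respondents, disp = survey
    d = disp.set_index(["frame", "code"])["count"]
    per_complete_ll = field_config.n_landline / d[("landline", "I")]
    per_complete_cell = field_config.n_cell / d[("cell", "I")]
    assert per_complete_ll > per_complete_cell
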