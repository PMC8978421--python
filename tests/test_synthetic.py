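"""Synthetic population generator: shares, equipment gradients, frames."""

import numpy as np
import pandas as pd
import pytest

import rddframes as rf
from rddframes.synthetic import AGE_BANDS, _frame_size


def test_generation_is_deterministic(pop_config):
    p1, h1 = rf.generate_population(pop_config)
    p2, h2 = rf.generate_population(pop_config)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(h1, h2)


def test_households_partition_population(population):
    persons, households = population
    assert households["size"].sum() == len(persons)
    assert persons.groupby("household_id").size().equals(
        households.set_index("household_id")["size"])
    # every person in exactly one household
    assert persons["household_id"].notna().all()


def test_phone_coverage_strata_are_exhaustive(population):
    persons, _ = population
    cls = persons["phone_class"]
    assert set(cls.unique()) <= {"both", "cell_only", "landline_only", "phoneless"}
    assert ((persons["n_cell"] > 0) == cls.isin(["both", "cell_only"])).all()
    assert ((persons["n_landline"] > 0) == cls.isin(["both", "landline_only"])).all()


def test_eligible_counts_consistent(population):
    persons, _ = population
    assert (persons["e_ll"] >= 1).all()
    ll_owners = persons.loc[persons["n_landline"] > 0]
    # landline counts are household-level: identical within household
    assert (ll_owners.groupby("household_id")["n_landline"].nunique() == 1).all()


@pytest.mark.parametrize("variable", ["sex", "age_band", "education",
                                      "urbanization", "region"])
def test_realized_shares_match_model(population, pop_config, variable):
    """Realized category shares lie within 4*sqrt(p(1-p)/n) of config shares."""
    persons, _ = population
    n = len(persons)
    realized = persons[variable].value_counts(normalize=True)
    for cat, p in pop_config.category_shares[variable].items():
        bound = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(realized.get(cat, 0.0) - p) < bound, (variable, cat)


def test_cell_ownership_matches_implied_marginal():
    """Realized cell ownership within 3 SE of the exact mixture marginal."""
    cfg = rf.PopulationConfig(population_size=100_000, seed=1)
    persons, _ = rf.generate_population(cfg)
    implied = rf.implied_equipment_rate(cfg, "cell")
    se = np.sqrt(implied * (1 - implied) / len(persons))
    assert abs((persons["n_cell"] > 0).mean() - implied) < 3 * se


def test_equipment_gradient_direction(population):
    """Cell ownership decreases with age; landline increases with age."""
    persons, _ = population
    cell_by_age = persons.groupby("age_band")["n_cell"].apply(lambda s: (s > 0).mean())
    ll_by_age = persons.groupby("age_band")["n_landline"].apply(lambda s: (s > 0).mean())
    assert cell_by_age[AGE_BANDS[0]] > cell_by_age[AGE_BANDS[-1]]
    assert ll_by_age[AGE_BANDS[0]] < ll_by_age[AGE_BANDS[-1]]


def test_degenerate_equipment_model_all_cell():
    cfg = rf.PopulationConfig(population_size=500, seed=2)
    cfg.equipment_model["cell_base_by_age"] = {b: 1.0 for b in AGE_BANDS}
    cfg.equipment_model["landline_base_by_age"] = {b: 0.0 for b in AGE_BANDS}
    persons, _ = rf.generate_population(cfg)
    assert (persons["n_cell"] >= 1).all()
    assert (persons["n_landline"] == 0).all()


def test_invalid_config_rejected():
    cfg = rf.PopulationConfig(population_size=0)
    with pytest.raises(rf.ConfigError):
        rf.generate_population(cfg)
    cfg = rf.PopulationConfig(population_size=10)
    cfg.category_shares["sex"] = {"male": 0.6, "female": 0.6}
    with pytest.raises(rf.ConfigError):
        rf.generate_population(cfg)


def test_frame_size_arithmetic():
    assert _frame_size(70, 0.5) == 140
    assert _frame_size(67, 0.33) == 100  # round(67/0.67)
    assert _frame_size(70, 0.0) == 70
    with pytest.raises(rf.ConfigError):
        _frame_size(10, 1.0)


def test_frames_attach_every_number(population, frames):
    persons, households = population
    working_ll = frames.landline["household_id"].notna().sum()
    assert working_ll == households["n_landline"].sum()
    working_cell = frames.cell["person_id"].notna().sum()
    assert working_cell == persons["n_cell"].sum()
    assert frames.N_ll >= working_ll and frames.N_cell >= working_cell
    # realized non-working rates match the configured ones
    assert (frames.N_ll - working_ll) / frames.N_ll == pytest.approx(0.50, abs=1e-3)
    assert (frames.N_cell - working_cell) / frames.N_cell == pytest.approx(0.33, abs=1e-3)


def test_reference_margins_count_exactly():
    persons = pd.DataFrame({"person_id": range(10),
                            "sex": ["male"] * 5 + ["female"] * 5})
    (margin,) = rf.reference_margins(persons, ["sex"])
    assert margin.share("male") == 0.5 and margin.share("female") == 0.5
    with pytest.raises(rf.ConfigError):
        rf.reference_margins(persons, ["nope"])


def test_margins_sum_to_one(margins):
    for m in margins:
        assert sum(m.shares) == pytest.approx(1.0, abs=1e-9)
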