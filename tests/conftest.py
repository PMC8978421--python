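"""Shared fixtures: one moderately sized simulated survey reused across tests."""

import numpy as np
import pandas as pd
import pytest

import rddframes as rf


@pytest.fixture(scope="session")
def pop_config():
    return rf.PopulationConfig(population_size=20_000, seed=7)


@pytest.fixture(scope="session")
def population(pop_config):
    return rf.generate_population(pop_config)


@pytest.fixture(scope="session")
def frames(population):
    persons, households = population
    return rf.build_frames(persons, households)


@pytest.fixture(scope="session")
def field_config():
    return rf.FieldworkConfig(n_landline=3000, n_cell=4500, seed=13)


@pytest.fixture(scope="session")
def survey(population, frames, field_config, pop_config):
    """(respondents, dispositions) of one simulated wave."""
    persons, _ = population
    return rf.simulate_calls(frames, persons, field_config, pop_config)


@pytest.fixture(scope="session")
def sample_design(frames, field_config):
    return rf.SampleDesign(field_config.n_landline, frames.N_ll,
                           field_config.n_cell, frames.N_cell)


@pytest.fixture(scope="session")
def margins(population):
    persons, _ = population
    return rf.reference_margins(
        persons, ["sex_age", "education", "household_size", "urbanization",
                  "region"])


@pytest.fixture(scope="session")
def fitted():
    """A full fitted comparison on the default synthetic scenario.

    Uses the generator and fieldwork defaults untouched: these are the study
    conditions the direction checks (deft and weight-CV orderings) refer to.
    """
    model = rf.FrameComparison.from_simulation(rf.PopulationConfig(),
                                               rf.FieldworkConfig())
    return model.fit()


@pytest.fixture
def toy_respondents():
    """Hand-sized respondent table for arithmetic checks."""
    return pd.DataFrame({
        "person_id": [0, 1, 2, 3, 4],
        "frame": ["cell", "cell", "landline", "landline", "cell"],
        "t_ll": [0, 1, 1, 2, 0],
        "t_cell": [1, 1, 1, 0, 2],
        "e_ll": [1, 2, 2, 3, 1],
        "e_cell": [1, 1, 1, 1, 1],
        "smoker": [1, 0, 1, 0, 0],
    })
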