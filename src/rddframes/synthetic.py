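"""Synthetic population, telephone frames, and reference margins.

This module generates a finite population of adults aged 18-75 with the joint
structure a dual-frame random-digit-dialing (RDD) health survey assumes:

* demographic categories (sex x age band, education, household size,
  urbanization, region) drawn from configurable reference shares patterned on
  the French 18-75 population;
* telephone equipment with realistic gradients -- cell-phone ownership is a
  person-level attribute that decreases with age and increases with education
  (~96% overall by default), landline ownership is a household-level attribute
  that increases with age (~77% overall by default) -- so the population
  partitions into cell-only, landline-only, both, and phoneless strata;
* per-frame phone-number multiplicities (t), household eligible counts (e),
  latent binary health indicators whose prevalence depends on demographics and
  optionally on phone-equipment class beyond demographics, and per-frame
  contact/cooperation propensities.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Category systems
# ---------------------------------------------------------------------------

SEXES = ("male", "female")
AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-75")
AGE_BOUNDS = {
    "18-24": (18, 24),
    "25-34": (25, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    "65-75": (65, 75),
}
EDUCATION_LEVELS = (
    "primary",
    "less_than_high_school",
    "high_school",
    "post_secondary_2y",
    "post_secondary_3_4y",
    "post_secondary_5y_plus",
)
HOUSEHOLD_SIZES = ("1", "2", "3", "4", "5+")
URBANIZATION_LEVELS = (
    "rural",
    "lt_20k",
    "20k_100k",
    "100k_200k",
    "ge_200k",
    "paris",
)
REGIONS = (
    "Ile-de-France",
    "Grand-Est",
    "Hauts-de-France",
    "Normandie",
    "Centre",
    "Bourgogne-Franche-Comte",
    "Bretagne",
    "Pays-de-Loire",
    "Nouvelle-Aquitaine",
    "Auvergne-Rhone-Alpes",
    "Occitanie",
    "PACA-Corse",
)

HEALTH_INDICATORS = (
    "poor_health",
    "chronic_disease",
    "activity_limitation",
    "obesity",
    "physical_inactivity",
    "daily_smoking",
    "suicide_attempt",
)

PHONE_CLASSES = ("both", "cell_only", "landline_only", "phoneless")

#: Balance / calibration variables available on every person record.
BALANCE_VARIABLES = (
    "sex",
    "age_band",
    "sex_age",
    "education",
    "household_size",
    "urbanization",
    "region",
    "phone_class",
)


def _normalized(labels: Sequence[str], raw: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(raw, dtype=float)
    arr = arr / arr.sum()
    return dict(zip(labels, arr))


# ---------------------------------------------------------------------------
# Margin tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginTable:
    """Reference population shares for one categorical variable."""

    variable: str
    categories: tuple[str, ...]
    shares: tuple[float, ...]

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ConfigError(f"margin '{self.variable}': duplicate categories")
        shares = np.asarray(self.shares, dtype=float)
        if np.any(shares < 0) or np.any(shares > 1):
            raise ConfigError(f"margin '{self.variable}': shares outside [0, 1]")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"margin '{self.variable}': shares sum to {shares.sum():.12f}, not 1"
            )

    @classmethod
    def from_shares(cls, variable: str, shares: Mapping[str, float],
                    normalize: bool = False) -> "MarginTable":
        cats = tuple(shares.keys())
        vals = np.asarray(list(shares.values()), dtype=float)
        if normalize:
            vals = vals / vals.sum()
        return cls(variable, cats, tuple(float(v) for v in vals))

    @classmethod
    def from_values(cls, variable: str, values: Iterable[str]) -> "MarginTable":
        counts = pd.Series(list(values)).value_counts(sort=False)
        shares = counts / counts.sum()
        return cls(variable, tuple(str(c) for c in shares.index),
                   tuple(float(v) for v in shares.values))

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, index=list(self.categories),
                         name=self.variable)

    def share(self, category: str) -> float:
        return self.shares[self.categories.index(category)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_category_shares() -> dict[str, dict[str, float]]:
    # French 18-75 reference structure (Labor-Force-Survey-like margins).
    return {
        "sex": _normalized(SEXES, [48.7, 51.3]),
        "age_band": _normalized(AGE_BANDS, [11.2, 17.1, 18.5, 19.5, 18.2, 15.5]),
        "education": _normalized(
            EDUCATION_LEVELS, [13.3, 35.4, 20.4, 12.8, 7.6, 10.5]
        ),
        "household_size": _normalized(HOUSEHOLD_SIZES, [17.4, 34.2, 18.9, 19.3, 10.2]),
        "urbanization": _normalized(
            URBANIZATION_LEVELS, [24.0, 16.8, 12.1, 4.9, 25.7, 16.6]
        ),
        "region": _normalized(
            REGIONS, [19.0, 8.6, 9.3, 5.1, 4.0, 4.4, 5.1, 5.7, 9.2, 12.2, 9.1, 8.3]
        ),
    }


def _default_equipment_model() -> dict:
    # Cell ownership ~96% overall, decreasing with age, increasing with
    # education; landline ~77% overall, increasing with age. Education enters
    # as a log-odds offset on the age-band baseline.
    return {
        "cell_base_by_age": dict(zip(AGE_BANDS, [0.995, 0.99, 0.985, 0.975, 0.95, 0.87])),
        "landline_base_by_age": dict(zip(AGE_BANDS, [0.58, 0.62, 0.72, 0.82, 0.89, 0.93])),
        "cell_edu_logodds": dict(zip(EDUCATION_LEVELS, [-0.9, -0.3, 0.0, 0.3, 0.6, 0.9])),
        "landline_edu_logodds": dict(zip(EDUCATION_LEVELS, [-0.2, -0.1, 0.0, 0.1, 0.2, 0.3])),
    }


def _default_health_model() -> dict[str, dict]:
    ages = AGE_BANDS
    edus = EDUCATION_LEVELS

    def m(base, age_lo, edu_lo, phone_lo=None):
        return {
            "base": base,
            "age_logodds": dict(zip(ages, age_lo)),
            "edu_logodds": dict(zip(edus, edu_lo)),
            "phone_logodds": phone_lo or {},
        }

    return {
        "poor_health": m(0.060, [-1.0, -0.6, -0.2, 0.2, 0.5, 0.7],
                         [0.6, 0.3, 0.0, -0.2, -0.4, -0.5]),
        "chronic_disease": m(0.366, [-0.9, -0.6, -0.3, 0.1, 0.5, 0.8],
                             [0.3, 0.15, 0.0, -0.1, -0.2, -0.25]),
        "activity_limitation": m(0.216, [-0.8, -0.5, -0.2, 0.1, 0.4, 0.6],
                                 [0.4, 0.2, 0.0, -0.1, -0.3, -0.4]),
        "obesity": m(0.135, [-0.6, -0.3, 0.0, 0.2, 0.3, 0.3],
                     [0.5, 0.25, 0.0, -0.2, -0.4, -0.6]),
        "physical_inactivity": m(0.087, [-0.3, -0.2, 0.0, 0.1, 0.2, 0.3],
                                 [0.6, 0.3, 0.0, -0.2, -0.4, -0.5]),
        # Residual phone-equipment effects beyond demographics: daily smoking
        # and lifetime suicidal attempts are more prevalent among cell-only
        # people even at fixed age/education.
        "daily_smoking": m(0.270, [0.5, 0.4, 0.2, 0.0, -0.5, -1.0],
                           [0.5, 0.3, 0.0, -0.2, -0.5, -0.7],
                           {"cell_only": 0.18, "landline_only": -0.25}),
        "suicide_attempt": m(0.072, [0.0, 0.1, 0.1, 0.1, 0.0, -0.1],
                             [0.5, 0.25, 0.0, -0.2, -0.4, -0.5],
                             {"cell_only": 0.15, "landline_only": -0.15}),
    }


def _default_response_model() -> dict:
    # Per-call answer probability by frame and age band, and cooperation
    # probability given contact. Elderly answer landlines readily; cell
    # answer rates decline slightly with age.
    return {
        "contact_per_call": {
            "landline": dict(zip(AGE_BANDS, [0.10, 0.12, 0.15, 0.20, 0.26, 0.32])),
            "cell": dict(zip(AGE_BANDS, [0.26, 0.25, 0.24, 0.23, 0.22, 0.20])),
        },
        "cooperation_by_age": dict(zip(AGE_BANDS, [0.50, 0.52, 0.55, 0.58, 0.62, 0.66])),
    }


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population generator.

    Defaults emulate the French 18-75 general population as seen by a national
    telephone health survey: the demographic margins, the ~96% cell / ~77%
    landline equipment rates with their age and education gradients, and
    plausible phone-number multiplicity and response-propensity models.
    """

    population_size: int = 50_000
    category_shares: dict[str, dict[str, float]] = field(
        default_factory=_default_category_shares
    )
    equipment_model: dict = field(default_factory=_default_equipment_model)
    # P(k numbers | owns >=1 number in the frame), per frame.
    n_phone_numbers_model: dict[int, float] = field(
        default_factory=lambda: {1: 0.90, 2: 0.09, 3: 0.01}
    )
    health_model: dict[str, dict] = field(default_factory=_default_health_model)
    response_model: dict = field(default_factory=_default_response_model)
    misreport_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 1:
            raise ConfigError("population_size must be >= 1")
        for var, shares in self.category_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"category shares for '{var}' sum to {total:.12f}, not 1"
                )
            if any(s < 0 or s > 1 for s in shares.values()):
                raise ConfigError(f"category shares for '{var}' outside [0, 1]")
        if abs(sum(self.n_phone_numbers_model.values()) - 1.0) > 1e-9:
            raise ConfigError("n_phone_numbers_model probabilities must sum to 1")
        for key in ("cell_base_by_age", "landline_base_by_age"):
            for band, p in self.equipment_model[key].items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"equipment_model[{key}][{band}] outside [0, 1]")
        if not 0.0 <= self.misreport_rate <= 1.0:
            raise ConfigError("misreport_rate outside [0, 1]")
        for ind, model in self.health_model.items():
            if not 0.0 < model["base"] < 1.0:
                raise ConfigError(f"health_model[{ind}]['base'] must be in (0, 1)")

    def with_seed(self, seed: int) -> "PopulationConfig":
        return replace(self, seed=seed)


def _ownership_prob(base_by_age: Mapping[str, float],
                    edu_logodds: Mapping[str, float],
                    age_band, education) -> np.ndarray:
    """P(owns phone | age band, education): logistic shift of the age baseline."""
    base = np.asarray([base_by_age[a] for a in np.atleast_1d(age_band)])
    off = np.asarray([edu_logodds.get(e, 0.0) for e in np.atleast_1d(education)])
    p = np.where(base >= 1.0, 1.0, np.where(base <= 0.0, 0.0,
                 expit(logit(np.clip(base, 1e-12, 1 - 1e-12)) + off)))
    return p


def implied_equipment_rate(config: PopulationConfig, frame: str) -> float:
    """Model-implied marginal ownership rate by exact summation over strata.

    Age band and education are independent in the generator, so the marginal
    is the share-weighted mixture of the per-(age, education) probabilities.
    For the landline frame this is the household-head-level rate, which also
    approximates the person-level rate because heads are population draws.
    """
    if frame == "cell":
        base = config.equipment_model["cell_base_by_age"]
        off = config.equipment_model["cell_edu_logodds"]
    elif frame == "landline":
        base = config.equipment_model["landline_base_by_age"]
        off = config.equipment_model["landline_edu_logodds"]
    else:
        raise ConfigError(f"unknown frame '{frame}'")
    age_shares = config.category_shares["age_band"]
    edu_shares = config.category_shares["education"]
    total = 0.0
    for band, pa in age_shares.items():
        for edu, pe in edu_shares.items():
            total += pa * pe * float(_ownership_prob(base, off, band, edu)[0])
    return total


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


def _draw_categorical(rng, shares: Mapping[str, float], n: int) -> np.ndarray:
    cats = np.array(list(shares.keys()), dtype=object)
    p = np.array(list(shares.values()), dtype=float)
    return rng.choice(cats, size=n, p=p / p.sum())


_SIZE_LABEL = {1: "1", 2: "2", 3: "3", 4: "4"}


def _household_size_label(size: int) -> str:
    return _SIZE_LABEL.get(int(size), "5+")


def generate_population(config: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic population.

    Returns ``(persons, households)``. Household formation draws a size class
    per person from the household-size margin, then groups persons of each
    class into households after sorting on jittered age, which induces the
    intra-household age correlation (couples and flatmates are age-alike)
    that makes the landline eligible count e vary realistically. All
    generated persons are aged 18-75 and eligible, so e equals the household
    size.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    shares = config.category_shares

    sex = _draw_categorical(rng, shares["sex"], n)
    age_band = _draw_categorical(rng, shares["age_band"], n)
    lo = np.array([AGE_BOUNDS[b][0] for b in age_band])
    hi = np.array([AGE_BOUNDS[b][1] for b in age_band])
    age = rng.integers(lo, hi + 1)
    education = _draw_categorical(rng, shares["education"], n)
    urbanization = _draw_categorical(rng, shares["urbanization"], n)
    region = _draw_categorical(rng, shares["region"], n)
    size_class = _draw_categorical(rng, shares["household_size"], n)

    # --- household formation -------------------------------------------------
    age_idx = np.array([AGE_BANDS.index(b) for b in age_band], dtype=float)
    household_id = np.empty(n, dtype=np.int64)
    next_hid = 0
    for label, target in zip(HOUSEHOLD_SIZES, (1, 2, 3, 4, 5)):
        members = np.flatnonzero(size_class == label)
        if members.size == 0:
            continue
        order = members[np.argsort(age_idx[members] + rng.normal(0, 0.75, members.size))]
        n_full, rem = divmod(order.size, target)
        hids = np.repeat(np.arange(n_full), target)
        if rem:
            hids = np.concatenate([hids, np.full(rem, n_full)])
        household_id[order] = next_hid + hids
        next_hid += n_full + (1 if rem else 0)

    hh_sizes = pd.Series(household_id).value_counts().sort_index()
    e_ll = hh_sizes.reindex(household_id).to_numpy()
    household_size = np.array([_household_size_label(s) for s in e_ll], dtype=object)

    # --- telephone equipment -------------------------------------------------
    eq = config.equipment_model
    p_cell = _ownership_prob(eq["cell_base_by_age"], eq["cell_edu_logodds"],
                             age_band, education)
    owns_cell = rng.random(n) < p_cell

    # Landline ownership decided once per household from its head (first member).
    head_idx = pd.Series(np.arange(n)).groupby(household_id).min().to_numpy()
    p_ll_head = _ownership_prob(eq["landline_base_by_age"], eq["landline_edu_logodds"],
                                age_band[head_idx], education[head_idx])
    hh_has_ll = rng.random(head_idx.size) < p_ll_head

    counts = np.array(sorted(config.n_phone_numbers_model))
    count_p = np.array([config.n_phone_numbers_model[k] for k in counts], dtype=float)
    hh_n_ll = np.where(hh_has_ll, rng.choice(counts, size=head_idx.size, p=count_p), 0)
    n_landline = pd.Series(hh_n_ll, index=pd.Series(household_id[head_idx])) \
        .reindex(household_id).to_numpy()
    n_cell = np.where(owns_cell, rng.choice(counts, size=n, p=count_p), 0)

    phone_class = np.select(
        [(n_cell > 0) & (n_landline > 0), (n_cell > 0), (n_landline > 0)],
        ["both", "cell_only", "landline_only"], default="phoneless",
    )

    # --- latent health indicators --------------------------------------------
    persons = pd.DataFrame({
        "person_id": np.arange(n),
        "household_id": household_id,
        "sex": sex,
        "age_band": age_band,
        "age": age,
        "sex_age": np.char.add(np.char.add(sex.astype(str), "|"), age_band.astype(str)),
        "education": education,
        "household_size": household_size,
        "urbanization": urbanization,
        "region": region,
        "e_ll": e_ll.astype(int),
        "n_landline": n_landline.astype(int),
        "n_cell": n_cell.astype(int),
        "phone_class": phone_class,
    })

    for ind, model in config.health_model.items():
        eta = logit(model["base"])
        eta = eta + np.array([model["age_logodds"].get(b, 0.0) for b in age_band])
        eta = eta + np.array([model["edu_logodds"].get(e, 0.0) for e in education])
        eta = eta + np.array([model["phone_logodds"].get(c, 0.0) for c in phone_class])
        persons[ind] = (rng.random(n) < expit(eta)).astype(int)

    rm = config.response_model
    persons["contact_ll"] = np.array(
        [rm["contact_per_call"]["landline"][b] for b in age_band])
    persons["contact_cell"] = np.array(
        [rm["contact_per_call"]["cell"][b] for b in age_band])
    persons["coop"] = np.array([rm["cooperation_by_age"][b] for b in age_band])

    households = pd.DataFrame({
        "household_id": household_id[head_idx],
        "size": e_ll[head_idx].astype(int),
        "n_landline": hh_n_ll.astype(int),
    }).sort_values("household_id").reset_index(drop=True)

    return persons, households


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------


@dataclass
class FrameSpec:
    """The two RDD sampling frames: lists of telephone numbers.

    Working landline numbers map to households; working cell numbers map to
    persons; the remainder of each frame is non-working (padding the frame up
    to the configured non-working rate, ~50% landline / ~33% cell by default).
    """

    landline: pd.DataFrame  # columns: number_id, household_id (<NA> = non-working)
    cell: pd.DataFrame      # columns: number_id, person_id (<NA> = non-working)
    nonworking_rate_ll: float
    nonworking_rate_cell: float

    @property
    def N_ll(self) -> int:
        return len(self.landline)

    @property
    def N_cell(self) -> int:
        return len(self.cell)


def _frame_size(n_working: int, nonworking_rate: float) -> int:
    """Total frame size so the non-working share hits the configured rate.

    N = round(working / (1 - rate)); e.g. 70 working at rate 0.5 -> N = 140,
    67 working at rate 0.33 -> round(100.0) = 100.
    """
    if not 0.0 <= nonworking_rate <= 1.0:
        raise ConfigError("nonworking rate outside [0, 1]")
    if nonworking_rate == 1.0:
        if n_working > 0:
            raise ConfigError("nonworking rate of 1 with working numbers present")
        return 0
    return int(round(n_working / (1.0 - nonworking_rate)))


def build_frames(persons: pd.DataFrame, households: pd.DataFrame,
                 nonworking_rate_ll: float = 0.50,
                 nonworking_rate_cell: float = 0.33) -> FrameSpec:
    """Construct the landline and cell RDD frames from the population."""
    ll_owner = households.loc[households["n_landline"] > 0]
    ll_hh = np.repeat(ll_owner["household_id"].to_numpy(),
                      ll_owner["n_landline"].to_numpy())
    n_ll_working = ll_hh.size
    N_ll = _frame_size(n_ll_working, nonworking_rate_ll)
    landline = pd.DataFrame({
        "number_id": np.arange(N_ll),
        "household_id": pd.array(
            np.concatenate([ll_hh, np.full(N_ll - n_ll_working, -1)]),
            dtype="Int64"),
    })
    landline.loc[landline["household_id"] == -1, "household_id"] = pd.NA

    cell_owner = persons.loc[persons["n_cell"] > 0]
    cell_pid = np.repeat(cell_owner["person_id"].to_numpy(),
                         cell_owner["n_cell"].to_numpy())
    n_cell_working = cell_pid.size
    N_cell = _frame_size(n_cell_working, nonworking_rate_cell)
    cell = pd.DataFrame({
        "number_id": np.arange(N_cell),
        "person_id": pd.array(
            np.concatenate([cell_pid, np.full(N_cell - n_cell_working, -1)]),
            dtype="Int64"),
    })
    cell.loc[cell["person_id"] == -1, "person_id"] = pd.NA
    return FrameSpec(landline, cell, nonworking_rate_ll, nonworking_rate_cell)


def reference_margins(persons: pd.DataFrame,
                      variables: Sequence[str]) -> list[MarginTable]:
    """Exact population margins for the requested variables.

    These stand in for the external reference sources (labor-force survey /
    census) that anchor calibration and balance diagnostics.
    """
    tables = []
    for var in variables:
        if var not in persons.columns:
            raise ConfigError(f"unknown margin variable '{var}'")
        tables.append(MarginTable.from_values(var, persons[var]))
    return tables
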