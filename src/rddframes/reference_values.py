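"""Published aggregates of a national dual-frame RDD health survey (France, 2017).

The survey compared its realized dual-frame (DF, landline + cell, n = 25,319)
design with the counterfactual single-frame (SF, cell-only, n = 15,602)
design obtained by dropping the landline respondents. Its report tables print
category-level standardized distances, variable-level D values, per-indicator
deft values and prevalences. Those printed values are deterministic inputs to
the aggregation rules implemented in :mod:`rddframes.diagnostics` and
:mod:`rddframes.estimation`, and serve as worked examples: re-applying the
rules to the printed inputs must reproduce the printed aggregates (with
half-up rounding to the displayed precision).
"""

from __future__ import annotations

from ._util import round_half_up
from .diagnostics import mean_distance, variable_distance
from .estimation import relative_difference

# Category-level standardized distances d (percent) for the calibration
# covariates, per design, as printed (signed; aggregation uses |d|).
CALIBRATION_CATEGORY_D: dict[str, dict[str, list[float]]] = {
    "DF": {
        "sex": [-5.6, 5.6],
        "age": [-2.3, 0.5, -2.3, -1.5, 2.6, 2.7],
        "education": [-19.8, -8.9, 3.2, -0.6, 22.4, 6.6],
        "household_size": [14.7, 2.5, -6.0, -8.4, -5.5],
        "urbanization": [2.3, -0.8, 2.1, 4.4, -4.2, -1.9],
        "region": [-2.8, -0.4, -2.5, 1.3, -1.0, -0.5, 3.9, -0.9, 1.0, 3.0, 1.4, -1.5],
    },
    "SF": {
        "sex": [-3.0, 3.0],
        "age": [1.3, 5.2, 0.8, -0.3, 0.5, -8.1],
        "education": [-22.9, -14.6, 5.6, 1.8, 24.1, 9.5],
        "household_size": [12.3, -2.3, -2.3, -5.4, -2.7],
        "urbanization": [-2.8, -1.9, 1.8, 4.8, -1.4, 2.1],
        "region": [1.6, -1.9, -2.4, -0.8, -2.1, -1.7, 3.2, -2.6, 0.9, 1.8, 1.5, 0.2],
    },
}

# Variable-level D values as printed for the calibration covariates.
CALIBRATION_VARIABLE_D: dict[str, dict[str, float]] = {
    "DF": {"sex": 5.6, "age": 2.0, "education": 10.3, "household_size": 7.4,
           "urbanization": 2.6, "region": 1.7},
    "SF": {"sex": 3.0, "age": 2.7, "education": 13.1, "household_size": 5.0,
           "urbanization": 2.5, "region": 1.7},
}

#: Printed sample-level mean D for the calibration covariates.
CALIBRATION_MEAN_D = {"DF": 4.9, "SF": 4.7}

# Variable-level D values for the external covariates (professional status,
# socio-professional group, family-physician visit), per design.
EXTERNAL_VARIABLE_D: dict[str, list[float]] = {
    "DF": [8.0, 2.9, 6.6],
    "SF": [7.8, 2.8, 8.2],
}

#: Printed sample-level mean D for the external covariates.
EXTERNAL_MEAN_D = {"DF": 5.8, "SF": 6.3}

# Per-indicator deft values of the whole-population comparison table.
INDICATORS = ("poor_health", "chronic_disease", "activity_limitation",
              "obesity", "physical_inactivity", "daily_smoking",
              "suicide_attempt")
DEFT: dict[str, dict[str, float]] = {
    "DF": dict(zip(INDICATORS, [1.30, 1.22, 1.23, 1.27, 1.32, 1.28, 1.28])),
    "SF": dict(zip(INDICATORS, [1.21, 1.13, 1.15, 1.17, 1.20, 1.14, 1.15])),
}

#: Printed mean deft per design.
MEAN_DEFT = {"DF": 1.27, "SF": 1.16}

# Printed prevalence pairs (DF %, SF %) with their printed relative
# differences, for the worked relative-difference examples.
RELATIVE_DIFFERENCE_EXAMPLES = {
    "poor_health": {"df": 6.0, "sf": 5.7, "printed": -5.0},
    "chronic_disease": {"df": 36.6, "sf": 36.3, "printed": -0.8},
    "activity_limitation_60_75": {"df": 31.2, "sf": 30.1, "printed": -3.5},
}


def reconstruct_variable_d(design: str) -> dict[str, float]:
    """Variable-level D from the printed category d values, at printed precision."""
    return {
        var: round_half_up(variable_distance(ds), 1)
        for var, ds in CALIBRATION_CATEGORY_D[design].items()
    }


def reconstruct_calibration_mean_d(design: str) -> float:
    """Sample-level mean D from the printed variable-level D values."""
    return round_half_up(
        mean_distance(list(CALIBRATION_VARIABLE_D[design].values())), 1)


def reconstruct_external_mean_d(design: str) -> float:
    """External-covariate mean D from the printed variable-level values."""
    return round_half_up(mean_distance(EXTERNAL_VARIABLE_D[design]), 1)


def reconstruct_mean_deft(design: str) -> float:
    """Mean deft from the seven printed per-indicator deft values."""
    vals = list(DEFT[design].values())
    return round_half_up(sum(vals) / len(vals), 2)


def reconstruct_relative_difference(key: str) -> float:
    """Relative difference from a printed (DF, SF) prevalence pair."""
    ex = RELATIVE_DIFFERENCE_EXAMPLES[key]
    return round_half_up(relative_difference(ex["sf"], ex["df"]), 1)
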