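"""Raking-ratio calibration (iterative proportional fitting) of survey weights.

Weights are cyclically multiplied, one calibration variable at a time, by the
ratio of the target category total to the current weighted category total,
until every margin is reproduced. Relative weights within each cell of the
full cross-classification are preserved. Margins are shares scaled to a
reference population total, so calibrated weights sum to the population size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, StructuralZeroError
from .synthetic import MarginTable

DEFAULT_TOLERANCE = 1e-8
DEFAULT_MAX_CYCLES = 100

#: The five default calibration variables: sex-by-age jointly, then the four
#: marginal variables.
DEFAULT_CALIBRATION_VARIABLES = (
    "sex_age", "education", "household_size", "urbanization", "region",
)


@dataclass
class RakingResult:
    """Outcome of one raking run."""

    weights: pd.Series
    iterations: int
    max_relative_deviation: float
    converged: bool
    population_total: float

    def __post_init__(self):
        if np.any(self.weights.to_numpy() <= 0):
            raise DataError("calibrated weights must be positive")


def _category_codes(values: pd.Series, margin: MarginTable) -> np.ndarray:
    cats = pd.Index(margin.categories)
    codes = cats.get_indexer(values.astype(str))
    if np.any(codes < 0):
        missing = sorted(set(values[codes < 0].astype(str)))
        raise DataError(
            f"sample categories {missing} of '{margin.variable}' absent from margin")
    return codes


def margin_deviation(weights, categories: pd.DataFrame,
                     margins: Sequence[MarginTable]) -> float:
    """Max over categories of |weighted share - target share| / target share.

    A zero-target category carrying positive weight is reported as ``inf``.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    worst = 0.0
    for margin in margins:
        codes = _category_codes(categories[margin.variable], margin)
        current = np.bincount(codes, weights=w, minlength=len(margin.categories))
        shares = current / total
        for share, target in zip(shares, margin.shares):
            if target == 0.0:
                if share > 0.0:
                    return float("inf")
                continue
            worst = max(worst, abs(share - target) / target)
    return worst


def rake(weights, categories: pd.DataFrame, margins: Sequence[MarginTable],
         population_total: float | None = None,
         tolerance: float = DEFAULT_TOLERANCE,
         max_cycles: int = DEFAULT_MAX_CYCLES) -> RakingResult:
    """Calibrate ``weights`` to the margins by the raking ratio.

    Parameters
    ----------
    weights : positive starting weights (typically design weights).
    categories : DataFrame with one column per margin variable.
    margins : target share tables; each must cover every sample category.
    population_total : reference population size the margins are scaled to.
        Defaults to the starting weight total (shares-only calibration).
    tolerance : stop when the max relative margin deviation falls below this.
    max_cycles : give up (with ``converged=False``) after this many full
        cycles over the margin list.
    """
    w = pd.Series(np.asarray(weights, dtype=float),
                  index=categories.index, name="calibrated_weight")
    if np.any(w.to_numpy() <= 0) or not np.all(np.isfinite(w.to_numpy())):
        raise DataError("starting weights must be positive finite")
    if population_total is None:
        population_total = float(w.sum())

    code_map = {m.variable: _category_codes(categories[m.variable], m)
                for m in margins}
    target_map = {m.variable: np.asarray(m.shares) * population_total
                  for m in margins}

    # Structural zeros are fatal up front: no multiplicative update can fill
    # an empty cell.
    for m in margins:
        counts = np.bincount(code_map[m.variable],
                             minlength=len(m.categories))
        for j, cat in enumerate(m.categories):
            if counts[j] == 0 and m.shares[j] > 0:
                raise StructuralZeroError(m.variable, cat)

    arr = w.to_numpy() * (population_total / w.sum())
    iterations = 0
    deviation = margin_deviation(arr, categories, margins)
    while deviation > tolerance and iterations < max_cycles:
        for m in margins:
            codes = code_map[m.variable]
            current = np.bincount(codes, weights=arr,
                                  minlength=len(m.categories))
            factors = np.ones_like(current)
            nonzero = current > 0
            factors[nonzero] = target_map[m.variable][nonzero] / current[nonzero]
            arr = arr * factors[codes]
        iterations += 1
        deviation = margin_deviation(arr, categories, margins)

    return RakingResult(
        weights=pd.Series(arr, index=categories.index, name="calibrated_weight"),
        iterations=iterations,
        max_relative_deviation=float(deviation),
        converged=bool(deviation <= tolerance),
        population_total=float(population_total),
    )
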