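"""Representativeness diagnostics: standardized distances and the R-indicator.

Two complementary views of how well a weighted sample matches its reference
population:

* **Standardized distance** d (univariate, per category): the difference
  between the weighted sample share and the reference share, scaled by the
  pooled binomial standard deviation and expressed in percent. Distances are
  aggregated by an unweighted mean of |d| over a variable's m categories
  (D_variable), then by an unweighted mean of D_variable over variables
  (mean D). |D| below 10% is conventionally read as acceptable balance.

* **R-indicator** (multivariate): R = 1 - 2 * S(rho_hat), where S is the
  population standard deviation of propensities predicted by a main-effects
  logistic model. R = 1 means every stratum is represented proportionally;
  lower values mean more selective samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_half_up
from .errors import ConvergenceError, DataError
from .synthetic import MarginTable

#: Conventional threshold below which |d| (in percent) reflects acceptable balance.
BALANCE_THRESHOLD = 10.0


def standardized_distance(p_a: float, p_b: float) -> float:
    """Standardized distance (percent) between reference and sample shares.

    d = 100 * (p_B - p_A) / sqrt((p_A*q_A + p_B*q_B) / 2), with q = 1 - p;
    p_A is the reference-population share, p_B the weighted sample share.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 <= p <= 1.0:
            raise DataError(f"{name}={p} outside [0, 1]")
    if p_a == p_b:
        return 0.0  # includes the degenerate equal-at-0-or-1 case, by continuity
    denom_sq = (p_a * (1.0 - p_a) + p_b * (1.0 - p_b)) / 2.0
    if denom_sq == 0.0:
        raise DataError("both shares degenerate (0 or 1) and unequal: d undefined")
    return 100.0 * (p_b - p_a) / math.sqrt(denom_sq)


def variable_distance(category_ds: Sequence[float]) -> float:
    """D_variable: unweighted mean of |d| over a variable's categories."""
    ds = np.asarray(category_ds, dtype=float)
    if ds.size == 0:
        raise DataError("no category distances")
    return float(np.mean(np.abs(ds)))


def mean_distance(variable_ds: Sequence[float]) -> float:
    """Sample-level mean D: unweighted mean of the per-variable D values."""
    ds = np.asarray(variable_ds, dtype=float)
    if ds.size == 0:
        raise DataError("no variable distances")
    return float(np.mean(ds))


@dataclass
class BalanceReport:
    """Category-, variable- and sample-level balance of one weighted sample."""

    design_label: str
    categories: pd.DataFrame   # variable, category, p_ref, p_sample, d
    variable_d: pd.Series      # D per variable
    mean_d: float

    def acceptable(self, threshold: float = BALANCE_THRESHOLD) -> bool:
        return bool(self.mean_d < threshold)

    def flagged_variables(self, threshold: float = BALANCE_THRESHOLD) -> list[str]:
        return list(self.variable_d.index[self.variable_d >= threshold])

    def rounded(self, ndigits: int = 1) -> pd.DataFrame:
        """Presentation table with half-up rounding, as report tables print."""
        out = self.categories.copy()
        out["p_ref"] = [round_half_up(100 * v, ndigits) for v in out["p_ref"]]
        out["d"] = [round_half_up(v, ndigits) for v in out["d"]]
        return out


def balance_report(categories: pd.DataFrame, weights,
                   margins: Sequence[MarginTable],
                   design_label: str = "",
                   from_rounded: bool = False) -> BalanceReport:
    """Compute the full balance report of a weighted sample against margins.

    ``from_rounded=True`` aggregates category |d| values after half-up
    rounding to one decimal, reproducing aggregates exactly as they appear in
    printed report tables.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(categories):
        raise DataError("weights and categories have different lengths")
    total = w.sum()
    rows = []
    var_ds = {}
    for margin in margins:
        values = categories[margin.variable].astype(str).to_numpy()
        sample_cats = set(values)
        unknown = sample_cats - set(margin.categories)
        if unknown:
            raise DataError(
                f"categories {sorted(unknown)} of '{margin.variable}' "
                f"absent from the reference margin")
        ds = []
        for cat, p_ref in zip(margin.categories, margin.shares):
            p_sample = float(w[values == cat].sum() / total)
            d = standardized_distance(p_ref, p_sample)
            rows.append({"variable": margin.variable, "category": cat,
                         "p_ref": p_ref, "p_sample": p_sample, "d": d})
            ds.append(round_half_up(d, 1) if from_rounded else d)
        var_ds[margin.variable] = variable_distance(ds)
    variable_d = pd.Series(var_ds, name="D")
    return BalanceReport(
        design_label=design_label,
        categories=pd.DataFrame(rows),
        variable_d=variable_d,
        mean_d=mean_distance(variable_d.to_numpy()),
    )


@dataclass
class RIndicatorResult:
    """Representativeness indicator with its propensity-model context."""

    r: float
    propensity_sd: float
    model_description: str
    propensities: pd.Series  # predicted response propensity over the benchmark

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise DataError(f"R-indicator {self.r} outside [0, 1]")


def r_indicator(sample: pd.DataFrame, sample_weights,
                benchmark: pd.DataFrame, covariates: Sequence[str],
                benchmark_weights=None) -> RIndicatorResult:
    """Model-based R-indicator of a sample against a benchmark population.

    The sample is stacked on the benchmark with a membership label and a
    main-effects logistic model is fitted (benchmark rows at their population
    weights, sample rows at their design weights normalized to the achieved
    sample size). Because the benchmark is the full population, the fitted
    membership odds n*f_sample(x) / (N*f_pop(x)) estimate the response
    propensity rho(x) directly; the propensity scale is the odds, capped at 1.
    R = 1 - 2 * S where S is the benchmark-weighted standard deviation of the
    predicted propensities.
    """
    for cov in covariates:
        for df, name in ((sample, "sample"), (benchmark, "benchmark")):
            if cov not in df.columns:
                raise DataError(f"covariate '{cov}' missing from {name}")
    n = len(sample)
    if n == 0 or len(benchmark) == 0:
        raise DataError("empty sample or benchmark")
    sw = np.ones(n) if sample_weights is None else np.asarray(sample_weights, float)
    bw = (np.ones(len(benchmark)) if benchmark_weights is None
          else np.asarray(benchmark_weights, float))

    stacked = pd.concat(
        [benchmark[list(covariates)], sample[list(covariates)]],
        ignore_index=True)
    member = np.concatenate([np.zeros(len(benchmark)), np.ones(n)])
    # Sample pseudo-counts sum to the achieved size n so the odds scale is
    # rho; design weights only reshape the sample distribution over x.
    freq = np.concatenate([bw, sw * (n / sw.sum())])

    X = pd.get_dummies(stacked.astype(str), drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.GLM(member, X, family=sm.families.Binomial(),
                     freq_weights=freq).fit(maxiter=200)
    except Exception as exc:  # perfect separation, singular matrix, ...
        raise ConvergenceError(
            f"propensity model failed ({exc}); consider coarsening covariates"
        ) from exc
    if not fit.converged:
        raise ConvergenceError("propensity model did not converge")

    p_member = np.asarray(fit.predict(X.iloc[: len(benchmark)]))
    p_member = np.clip(p_member, 1e-12, 1 - 1e-12)
    rho = np.clip(p_member / (1.0 - p_member), 0.0, 1.0)
    mean_rho = float(np.average(rho, weights=bw))
    sd_rho = float(math.sqrt(np.average((rho - mean_rho) ** 2, weights=bw)))
    return RIndicatorResult(
        r=float(np.clip(1.0 - 2.0 * sd_rho, 0.0, 1.0)),
        propensity_sd=sd_rho,
        model_description=(
            f"main-effects logistic membership model on {list(covariates)}; "
            f"benchmark n={len(benchmark)}, sample n={n}"),
        propensities=pd.Series(rho),
    )
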