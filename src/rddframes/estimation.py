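"""Design-comparison estimation: weighted prevalences, deft, AAPOR rates.

The prevalence estimator is the Hajek ratio mean ybar = sum(w*y)/sum(w); its
variance uses Taylor linearization under a with-replacement single-stage
approximation, treating calibrated weights as fixed:

    var(ybar) = sum(w_i^2 (y_i - ybar)^2) / (sum w_i)^2.

deft = sqrt(var(ybar) / (s^2/n)) with s^2 = p(1-p) for a binary indicator:
the ratio of the design-based standard error to the SE of a simple random
sample of the same size. The relative difference between the counterfactual
single-frame and the dual-frame estimate is 100*(ybar_sf - ybar_df)/ybar_df.
Response rates follow AAPOR formula #3, with the eligibility factor e for
unknown-eligibility numbers estimated by proportional allocation among
resolved numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import DataError


def weighted_prevalence(responses, weights) -> tuple[float, float]:
    """(ybar, SE) of a binary indicator under the Hajek ratio estimator."""
    y = np.asarray(responses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise DataError("empty response vector")
    if y.size != w.size:
        raise DataError("responses and weights differ in length")
    if np.any(w <= 0):
        raise DataError("weights must be positive")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DataError("responses must be binary")
    total = w.sum()
    ybar = float((w * y).sum() / total)
    var = float((w**2 * (y - ybar) ** 2).sum() / total**2)
    return ybar, math.sqrt(var)


def deft(ybar: float, var_ybar: float, n: int) -> float:
    """Square root of the design effect for a binary indicator."""
    if not 0.0 < ybar < 1.0:
        raise DataError("deft undefined for degenerate prevalence (0 or 1)")
    if var_ybar < 0:
        raise DataError("negative variance")
    if n < 2:
        raise DataError("deft requires n >= 2")
    srs_var = ybar * (1.0 - ybar) / n
    return math.sqrt(var_ybar / srs_var)


def relative_difference(ybar_sf: float, ybar_df: float) -> float:
    """Percent relative difference of the SF estimate against the DF estimate."""
    if ybar_df <= 0:
        raise DataError("relative difference undefined when the DF estimate is 0")
    return 100.0 * (ybar_sf - ybar_df) / ybar_df


# ---------------------------------------------------------------------------
# AAPOR outcome rates
# ---------------------------------------------------------------------------


@dataclass
class OutcomeRates:
    """AAPOR response rate 3 per frame and overall."""

    rr3: dict[str, float]          # frame label (and "overall") -> RR3
    eligibility_factor: dict[str, float]

    def __post_init__(self):
        for k, v in self.rr3.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"RR3[{k}]={v} outside [0, 1]")
        for k, v in self.eligibility_factor.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"e[{k}]={v} outside [0, 1]")


def aapor_rr3(counts: Mapping[str, int], e: float | None = None) -> tuple[float, float]:
    """AAPOR response rate 3 from disposition counts.

    RR3 = I / (I + P + R + NC + O + e*(UH + UO)). When ``e`` is not given it
    is estimated by proportional allocation: known-eligible over known-status
    numbers, e = (I+P+R+NC+O) / (I+P+R+NC+O+NE). Returns (RR3, e).
    """
    get = lambda k: float(counts.get(k, 0))
    if any(v < 0 for v in (get(c) for c in ("I", "P", "R", "NC", "O", "UH", "UO", "NE"))):
        raise DataError("negative disposition count")
    eligible = get("I") + get("P") + get("R") + get("NC") + get("O")
    unknown = get("UH") + get("UO")
    if e is None:
        resolved = eligible + get("NE")
        e = eligible / resolved if resolved > 0 else 1.0
    if not 0.0 <= e <= 1.0:
        raise DataError("eligibility factor outside [0, 1]")
    denom = eligible + e * unknown
    if denom == 0:
        raise DataError("zero RR3 denominator")
    return get("I") / denom, e


def outcome_rates(dispositions: pd.DataFrame) -> OutcomeRates:
    """Per-frame and overall RR3 from a tidy (frame, code, count) table."""
    rr3, efac = {}, {}
    pooled: dict[str, float] = {}
    for frame, sub in dispositions.groupby("frame"):
        counts = dict(zip(sub["code"], sub["count"].astype(float)))
        rr3[frame], efac[frame] = aapor_rr3(counts)
        for code, cnt in counts.items():
            pooled[code] = pooled.get(code, 0.0) + cnt
    rr3["overall"], efac["overall"] = aapor_rr3(pooled)
    return OutcomeRates(rr3=rr3, eligibility_factor=efac)


# ---------------------------------------------------------------------------
# Design comparison
# ---------------------------------------------------------------------------


def estimate_table(respondents: pd.DataFrame, weights,
                   indicators: Sequence[str],
                   subgroup: pd.Series | None = None) -> pd.DataFrame:
    """Prevalence, SE, deft and n for each indicator under one design.

    ``subgroup`` is an optional boolean mask; subgroup estimates reuse the
    full-sample weights (no re-calibration within the subgroup).
    """
    w = pd.Series(np.asarray(weights, dtype=float), index=respondents.index)
    if subgroup is not None:
        respondents = respondents.loc[subgroup]
        w = w.loc[subgroup]
    rows = []
    for ind in indicators:
        if ind not in respondents.columns:
            raise DataError(f"indicator '{ind}' missing from respondent data")
        ybar, se = weighted_prevalence(respondents[ind], w)
        n = len(respondents)
        rows.append({
            "indicator": ind,
            "prevalence": ybar,
            "se": se,
            "deft": deft(ybar, se**2, n) if 0.0 < ybar < 1.0 else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows).set_index("indicator")


def compare_designs(df_table: pd.DataFrame, sf_table: pd.DataFrame,
                    printed_precision: bool = False) -> pd.DataFrame:
    """Side-by-side DF vs SF estimates with relative differences.

    With ``printed_precision=True`` the relative difference is computed from
    prevalences rounded half-up to one decimal (in percent), matching how
    published tables derive it from their printed values.
    """
    missing = set(df_table.index).symmetric_difference(sf_table.index)
    if missing:
        raise DataError(f"indicators {sorted(missing)} present in only one design")
    out = df_table.add_prefix("df_").join(sf_table.add_prefix("sf_"))
    rel = []
    for ind in out.index:
        p_df, p_sf = out.loc[ind, "df_prevalence"], out.loc[ind, "sf_prevalence"]
        if printed_precision:
            p_df = round_half_up(100 * p_df, 1)
            p_sf = round_half_up(100 * p_sf, 1)
        rel.append(relative_difference(p_sf, p_df))
    out["relative_difference"] = rel
    return out


def mean_deft(table: pd.DataFrame, column: str = "deft",
              printed_precision: bool = False) -> float:
    """Mean of the per-indicator deft values of one design."""
    vals = table[column].to_numpy(dtype=float)
    if printed_precision:
        vals = np.array([round_half_up(v, 2) for v in vals])
    return float(np.mean(vals))
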