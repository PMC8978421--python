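"""Design weights for dual-frame and counterfactual single-frame RDD designs.

A respondent's dual-frame (DF) selection probability is the multiplicity
estimator

    pi_df = (n_LL / N_LL) * (t_LL / e_LL) + (n_C / N_C) * (t_C / e_C),

the expected number of completed interviews of that person: each of their
t_LL landline numbers is dialed with probability n_LL/N_LL and the Kish stage
selects them with probability 1/e_LL among the household's e_LL eligibles;
each of their t_C cell numbers is dialed with probability n_C/N_C and reaches
them directly (e_C = 1). The counterfactual single-frame (SF) cell design
keeps only the cell term and only cell-frame respondents. Design weights are
1/pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: Reported phone-number multiplicities above this cap are truncated, the
#: usual survey practice to limit weight extremes.
DEFAULT_MULTIPLICITY_CAP = 3


@dataclass(frozen=True)
class SampleDesign:
    """Frame and sample sizes of one survey wave."""

    n_ll: int
    N_ll: int
    n_cell: int
    N_cell: int

    def __post_init__(self):
        if self.N_cell <= 0 or self.n_cell <= 0:
            raise ConfigError("cell frame and sample sizes must be positive")
        if self.n_ll < 0 or self.N_ll < 0:
            raise ConfigError("landline sizes must be nonnegative")
        if self.N_ll > 0 and self.n_ll > self.N_ll:
            raise ConfigError("n_ll exceeds N_ll")
        if self.n_cell > self.N_cell:
            raise ConfigError("n_cell exceeds N_cell")

    @property
    def f_ll(self) -> float:
        return self.n_ll / self.N_ll if self.N_ll else 0.0

    @property
    def f_cell(self) -> float:
        return self.n_cell / self.N_cell


@dataclass
class WeightSet:
    """Per-respondent weights for a named design (DF or SF)."""

    design_label: str
    weights: pd.Series  # indexed by respondent row index

    def __post_init__(self):
        w = self.weights.to_numpy(dtype=float)
        if w.size and (not np.all(np.isfinite(w)) or np.any(w <= 0)):
            raise DataError(f"{self.design_label}: weights must be positive finite")

    @property
    def max_min_ratio(self) -> float:
        return weight_dispersion(self.weights)[0]

    @property
    def cv(self) -> float:
        return weight_dispersion(self.weights)[1]

    def summary(self) -> dict:
        return {
            "design": self.design_label,
            "n": int(len(self.weights)),
            "sum": float(self.weights.sum()),
            "max_min_ratio": self.max_min_ratio,
            "cv": self.cv,
        }


def _validated_multiplicities(t_ll, e_ll, t_cell, e_cell, cap):
    t_ll = np.minimum(np.asarray(t_ll, dtype=float), cap)
    t_cell = np.minimum(np.asarray(t_cell, dtype=float), cap)
    e_ll = np.asarray(e_ll, dtype=float)
    e_cell = np.asarray(e_cell, dtype=float)
    if np.any((t_ll > 0) & (e_ll <= 0)):
        raise DataError("t_ll > 0 with e_ll = 0: inconsistent household data")
    if np.any((t_cell > 0) & (e_cell <= 0)):
        raise DataError("t_cell > 0 with e_cell = 0")
    if np.any(t_ll < 0) or np.any(t_cell < 0):
        raise DataError("negative phone multiplicity")
    return t_ll, e_ll, t_cell, e_cell


def df_selection_probability(t_ll, e_ll, t_cell, e_cell, design: SampleDesign,
                             cap: int = DEFAULT_MULTIPLICITY_CAP):
    """Dual-frame selection probability; vectorized over respondents.

    Respondents with no numbers in a frame contribute zero for that frame's
    term. Probabilities above 1 signal mis-specified frame counts and raise.
    """
    t_ll, e_ll, t_cell, e_cell = _validated_multiplicities(
        t_ll, e_ll, t_cell, e_cell, cap)
    ll_term = np.where(t_ll > 0, design.f_ll * t_ll / np.where(e_ll > 0, e_ll, 1.0), 0.0)
    cell_term = np.where(t_cell > 0,
                         design.f_cell * t_cell / np.where(e_cell > 0, e_cell, 1.0),
                         0.0)
    pi = ll_term + cell_term
    if np.any(pi > 1.0):
        raise DataError("selection probability exceeds 1: check frame counts")
    return pi if np.ndim(pi) else float(pi)


def sf_selection_probability(t_cell, design: SampleDesign,
                             cap: int = DEFAULT_MULTIPLICITY_CAP):
    """Single-frame (cell-only) selection probability: (n_C/N_C) * t_C (e_C = 1)."""
    t_cell = np.minimum(np.asarray(t_cell, dtype=float), cap)
    if np.any(t_cell < 1):
        raise DataError("SF selection requires at least one cell number")
    pi = design.f_cell * t_cell
    if np.any(pi > 1.0):
        raise DataError("selection probability exceeds 1: check frame counts")
    return pi if np.ndim(pi) else float(pi)


def df_weights(respondents: pd.DataFrame, design: SampleDesign,
               cap: int = DEFAULT_MULTIPLICITY_CAP) -> WeightSet:
    """Dual-frame design weights 1/pi_df for the full respondent set."""
    if respondents.empty:
        raise DataError("empty respondent set")
    pi = df_selection_probability(
        respondents["t_ll"], respondents["e_ll"],
        respondents["t_cell"], respondents["e_cell"], design, cap)
    if np.any(pi <= 0):
        raise DataError("respondent with zero selection probability")
    return WeightSet("DF", pd.Series(1.0 / pi, index=respondents.index))


def build_counterfactual_sf(respondents: pd.DataFrame, design: SampleDesign,
                            cap: int = DEFAULT_MULTIPLICITY_CAP
                            ) -> tuple[pd.DataFrame, WeightSet]:
    """The as-if single-frame sample: cell-frame respondents with SF weights."""
    sf = respondents.loc[respondents["frame"] == "cell"]
    if sf.empty:
        raise DataError("no cell-frame respondents: cannot build SF design")
    pi = sf_selection_probability(sf["t_cell"], design, cap)
    return sf, WeightSet("SF", pd.Series(1.0 / pi, index=sf.index))


def weight_dispersion(weights) -> tuple[float, float]:
    """(max/min ratio, coefficient of variation) of a weight vector.

    CV uses the population standard deviation (divisor n); both statistics
    are invariant to rescaling all weights by a positive constant.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DataError("empty weight vector")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DataError("weights must be positive finite")
    return float(w.max() / w.min()), float(w.std(ddof=0) / w.mean())
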