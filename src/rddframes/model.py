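"""Model/results interface for the dual-frame vs single-frame comparison.

:class:`FrameComparison` bundles one survey wave -- respondent records, frame
and sample sizes, calibration margins, and optionally a benchmark population
and disposition tables -- and its :meth:`FrameComparison.fit` runs the whole
counterfactual analysis: design weights for the realized dual-frame (DF)
design and the as-if single-frame (SF) cell design, raking calibration of
both, balance diagnostics, R-indicators, AAPOR outcome rates, and the
prevalence/deft/relative-difference comparison overall and by age subgroup.
The returned :class:`FrameComparisonResults` carries every intermediate
object and renders a report-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up, spawn_seeds
from .calibration import (DEFAULT_CALIBRATION_VARIABLES, DEFAULT_MAX_CYCLES,
                          DEFAULT_TOLERANCE, RakingResult, rake)
from .diagnostics import BalanceReport, RIndicatorResult, balance_report, r_indicator
from .errors import DataError
from .estimation import (OutcomeRates, compare_designs, estimate_table,
                         mean_deft, outcome_rates)
from .fieldwork import FieldworkConfig, simulate_calls
from .synthetic import (HEALTH_INDICATORS, MarginTable, PopulationConfig,
                        build_frames, generate_population, reference_margins)
from .weighting import (SampleDesign, WeightSet, build_counterfactual_sf,
                        df_weights)

DEFAULT_SUBGROUPS: dict[str, tuple[int, int]] = {"18-30": (18, 30), "60-75": (60, 75)}
DEFAULT_PROPENSITY_COVARIATES = ("sex", "age_band", "education")


class FrameComparison:
    """One dual-frame survey wave and its counterfactual cell-only design.

    Parameters
    ----------
    respondents : complete-interview records with frame of origin, reported
        multiplicities (t_ll, t_cell), eligible counts (e_ll, e_cell),
        demographic categories, exact age, and binary health indicators.
    design : frame and sample sizes (n_LL, N_LL, n_C, N_C).
    margins : calibration margin tables covering the calibration variables.
    indicators : binary health indicators to estimate.
    benchmark : optional population microdata for R-indicators.
    dispositions : optional tidy (frame, code, count) table for outcome rates.
    external_margins : optional margins of covariates not used in calibration,
        diagnosed with calibrated weights.
    population_total : reference population size the calibrated weights are
        scaled to; defaults to the benchmark size, else the DF weight total.
    """

    def __init__(self, respondents: pd.DataFrame, design: SampleDesign,
                 margins: Sequence[MarginTable],
                 indicators: Sequence[str] = HEALTH_INDICATORS,
                 benchmark: pd.DataFrame | None = None,
                 dispositions: pd.DataFrame | None = None,
                 external_margins: Sequence[MarginTable] = (),
                 calibration_variables: Sequence[str] = DEFAULT_CALIBRATION_VARIABLES,
                 propensity_covariates: Sequence[str] = DEFAULT_PROPENSITY_COVARIATES,
                 subgroups: Mapping[str, tuple[int, int]] = DEFAULT_SUBGROUPS,
                 population_total: float | None = None):
        if respondents.empty:
            raise DataError("no respondents")
        margin_vars = {m.variable for m in margins}
        missing = [v for v in calibration_variables if v not in margin_vars]
        if missing:
            raise DataError(f"no margin supplied for calibration variables {missing}")
        self.respondents = respondents.reset_index(drop=True)
        self.design = design
        self.margins = [m for m in margins if m.variable in set(calibration_variables)]
        self.indicators = tuple(indicators)
        self.benchmark = benchmark
        self.dispositions = dispositions
        self.external_margins = list(external_margins)
        self.calibration_variables = tuple(calibration_variables)
        self.propensity_covariates = tuple(propensity_covariates)
        self.subgroups = dict(subgroups)
        if population_total is None:
            population_total = float(len(benchmark)) if benchmark is not None else None
        self.population_total = population_total

    # ------------------------------------------------------------------ build
    @classmethod
    def from_simulation(cls, pop_config: PopulationConfig,
                        field_config: FieldworkConfig,
                        nonworking_rate_ll: float = 0.50,
                        nonworking_rate_cell: float = 0.33,
                        **kwargs) -> "FrameComparison":
        """Simulate a population, its frames and fieldwork, then wrap them."""
        pop_seed, field_seed = spawn_seeds(pop_config.seed, 2)
        persons, households = generate_population(pop_config.with_seed(pop_seed))
        frames = build_frames(persons, households,
                              nonworking_rate_ll, nonworking_rate_cell)
        respondents, dispositions = simulate_calls(
            frames, persons, field_config.with_seed(field_seed), pop_config)
        design = SampleDesign(field_config.n_landline, frames.N_ll,
                              field_config.n_cell, frames.N_cell)
        calib_vars = kwargs.pop("calibration_variables",
                                DEFAULT_CALIBRATION_VARIABLES)
        margins = reference_margins(persons, calib_vars)
        external = reference_margins(persons, ["phone_class"])
        model = cls(respondents, design, margins,
                    benchmark=persons, dispositions=dispositions,
                    external_margins=external,
                    calibration_variables=calib_vars, **kwargs)
        model.population = persons
        model.households = households
        model.frames = frames
        return model

    # -------------------------------------------------------------------- fit
    def fit(self, tolerance: float = DEFAULT_TOLERANCE,
            max_cycles: int = DEFAULT_MAX_CYCLES) -> "FrameComparisonResults":
        """Run weighting, calibration, diagnostics and estimation."""
        resp = self.respondents
        dw = {"DF": df_weights(resp, self.design)}
        sf_resp, sf_ws = build_counterfactual_sf(resp, self.design)
        dw["SF"] = sf_ws
        samples = {"DF": resp, "SF": sf_resp}

        raking: dict[str, RakingResult] = {}
        calibrated: dict[str, WeightSet] = {}
        for label, sample in samples.items():
            res = rake(dw[label].weights, sample, self.margins,
                       population_total=self.population_total,
                       tolerance=tolerance, max_cycles=max_cycles)
            raking[label] = res
            calibrated[label] = WeightSet(f"{label}-calibrated", res.weights)

        # Balance of calibration covariates uses design weights (what the
        # sample looks like before calibration); external covariates use
        # calibrated weights.
        balance = {label: balance_report(samples[label], dw[label].weights,
                                         self.margins, design_label=label)
                   for label in samples}
        balance_external = {}
        if self.external_margins:
            balance_external = {
                label: balance_report(samples[label], calibrated[label].weights,
                                      self.external_margins, design_label=label)
                for label in samples}

        r_ind: dict[str, RIndicatorResult] = {}
        if self.benchmark is not None:
            for label, sample in samples.items():
                r_ind[label] = r_indicator(sample, dw[label].weights,
                                           self.benchmark,
                                           self.propensity_covariates)

        estimates: dict[str, pd.DataFrame] = {}
        tables = {}
        for label, sample in samples.items():
            tables[label] = {"all": estimate_table(sample,
                                                   calibrated[label].weights,
                                                   self.indicators)}
            for name, (lo, hi) in self.subgroups.items():
                mask = (sample["age"] >= lo) & (sample["age"] <= hi)
                tables[label][name] = estimate_table(
                    sample, calibrated[label].weights, self.indicators,
                    subgroup=mask)
        for scope in ["all", *self.subgroups]:
            estimates[scope] = compare_designs(tables["DF"][scope],
                                               tables["SF"][scope])

        rates = outcome_rates(self.dispositions) if self.dispositions is not None else None

        truth = None
        population = getattr(self, "population", None)
        if population is not None:
            truth = {
                "all": {ind: float(population[ind].mean())
                        for ind in self.indicators},
                "cell_covered": {
                    ind: float(population.loc[population["n_cell"] > 0, ind].mean())
                    for ind in self.indicators},
            }

        return FrameComparisonResults(
            model=self, design_weights=dw, raking=raking, calibrated=calibrated,
            balance=balance, balance_external=balance_external,
            r_indicators=r_ind, estimates=estimates, rates=rates,
            population_truth=truth)


@dataclass
class FrameComparisonResults:
    """Fitted quantities of a :class:`FrameComparison`."""

    model: FrameComparison
    design_weights: dict[str, WeightSet]
    raking: dict[str, RakingResult]
    calibrated: dict[str, WeightSet]
    balance: dict[str, BalanceReport]
    balance_external: dict[str, BalanceReport]
    r_indicators: dict[str, RIndicatorResult]
    estimates: dict[str, pd.DataFrame]   # scope ("all", "18-30", ...) -> table
    rates: OutcomeRates | None
    population_truth: dict | None = field(default=None)

    # ------------------------------------------------------------- accessors
    def weight_summary(self) -> pd.DataFrame:
        rows = [ws.summary() for ws in self.design_weights.values()]
        rows += [ws.summary() for ws in self.calibrated.values()]
        return pd.DataFrame(rows).set_index("design")

    def mean_deft(self, label: str) -> float:
        col = "df_deft" if label == "DF" else "sf_deft"
        return mean_deft(self.estimates["all"], column=col)

    def mean_d(self, label: str) -> float:
        return self.balance[label].mean_d

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        """Report-style text summary of the whole comparison."""
        lines = []
        m = self.model
        lines.append("Dual-frame vs single-frame cell RDD design comparison")
        lines.append("=" * 60)
        lines.append(
            f"Respondents: DF n={len(m.respondents)}, "
            f"SF n={int((m.respondents['frame'] == 'cell').sum())}")
        lines.append(
            f"Frames: landline n/N={m.design.n_ll}/{m.design.N_ll}, "
            f"cell n/N={m.design.n_cell}/{m.design.N_cell}")
        if self.rates is not None:
            rr = ", ".join(f"{k}={100 * v:.1f}%"
                           for k, v in self.rates.rr3.items())
            lines.append(f"AAPOR RR3: {rr}")
        lines.append("")
        lines.append("Weight dispersion")
        lines.append(self.weight_summary().round(4).to_string())
        lines.append("")
        lines.append("Balance of calibration covariates (design weights)")
        for label, rep in self.balance.items():
            lines.append(f"  {label}: mean D = {round_half_up(rep.mean_d, 1)}"
                         + (f"; R-indicator = {self.r_indicators[label].r:.2f}"
                            if label in self.r_indicators else ""))
            lines.append("  per-variable D: " + ", ".join(
                f"{v}={round_half_up(d, 1)}" for v, d in rep.variable_d.items()))
        if self.balance_external:
            lines.append("Balance of external covariates (calibrated weights)")
            for label, rep in self.balance_external.items():
                lines.append(f"  {label}: mean D = {round_half_up(rep.mean_d, 1)}")
        for scope, table in self.estimates.items():
            lines.append("")
            lines.append(f"Health indicator estimates ({scope})")
            disp = pd.DataFrame({
                "DF % (SE)": [f"{100 * p:.1f} ({100 * s:.1f})" for p, s in
                              zip(table["df_prevalence"], table["df_se"])],
                "DF deft": table["df_deft"].round(2),
                "SF % (SE)": [f"{100 * p:.1f} ({100 * s:.1f})" for p, s in
                              zip(table["sf_prevalence"], table["sf_se"])],
                "SF deft": table["sf_deft"].round(2),
                "rel diff %": table["relative_difference"].round(1),
            }, index=table.index)
            lines.append(disp.to_string())
        if self.estimates:
            lines.append("")
            lines.append(f"Mean deft: DF={self.mean_deft('DF'):.2f}, "
                         f"SF={self.mean_deft('SF'):.2f}")
        return "\n".join(lines)
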