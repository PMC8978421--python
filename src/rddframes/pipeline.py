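"""End-to-end experiment orchestration and Monte-Carlo replication.

``run_experiment`` drives one full counterfactual comparison from a single
:class:`RunConfig` (loadable from YAML): simulate population and fieldwork,
weight, calibrate, diagnose, estimate, compare, and write every intermediate
artifact as flat CSV/JSON plus a Markdown summary, all stamped with the
config hash and seed. ``replicate_study`` repeats the fieldwork over many
seeds on a fixed population to measure Monte-Carlo bias, empirical SE and
interval coverage of both designs against the synthetic truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import spawn_seeds
from .calibration import DEFAULT_CALIBRATION_VARIABLES, rake
from .errors import ConfigError
from .estimation import estimate_table
from .fieldwork import FieldworkConfig, simulate_calls
from .model import DEFAULT_SUBGROUPS, FrameComparison, FrameComparisonResults
from .synthetic import (HEALTH_INDICATORS, PopulationConfig, build_frames,
                        generate_population, reference_margins)
from .weighting import SampleDesign, build_counterfactual_sf, df_weights

logger = logging.getLogger("rddframes")

MARGINAL_CALIBRATION_VARIABLES = (
    "sex", "age_band", "education", "household_size", "urbanization", "region",
)


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    population: dict = field(default_factory=dict)   # PopulationConfig overrides
    fieldwork: dict = field(default_factory=dict)    # FieldworkConfig overrides
    nonworking_rate_ll: float = 0.50
    nonworking_rate_cell: float = 0.33
    margin_spec: str = "joint"        # "joint" sex-by-age or "marginal"
    indicators: Sequence[str] = HEALTH_INDICATORS
    subgroups: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    output_dir: str = "rddframes_output"
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if self.margin_spec not in ("joint", "marginal"):
            raise ConfigError("margin_spec must be 'joint' or 'marginal'")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__.keys()
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "subgroups" in raw:
            raw["subgroups"] = {k: tuple(v) for k, v in raw["subgroups"].items()}
        return cls(**raw)

    @property
    def calibration_variables(self) -> tuple[str, ...]:
        return (DEFAULT_CALIBRATION_VARIABLES if self.margin_spec == "joint"
                else MARGINAL_CALIBRATION_VARIABLES)

    def population_config(self, seed: int | None = None) -> PopulationConfig:
        cfg = PopulationConfig(**self.population)
        return cfg if seed is None else cfg.with_seed(seed)

    def fieldwork_config(self, seed: int | None = None) -> FieldworkConfig:
        cfg = FieldworkConfig(**self.fieldwork)
        return cfg if seed is None else cfg.with_seed(seed)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, start: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - start, extra)


def run_experiment(config: RunConfig,
                   write: bool = True) -> FrameComparisonResults:
    """Run the full counterfactual experiment; optionally write artifacts."""
    t0 = time.time()
    pop_cfg = config.population_config(config.seed)
    field_cfg = config.fieldwork_config()
    model = FrameComparison.from_simulation(
        pop_cfg, field_cfg,
        nonworking_rate_ll=config.nonworking_rate_ll,
        nonworking_rate_cell=config.nonworking_rate_cell,
        calibration_variables=config.calibration_variables,
        indicators=config.indicators,
        subgroups=config.subgroups,
    )
    _stage("simulate", t0, persons=len(model.population),
           respondents=len(model.respondents))
    t1 = time.time()
    results = model.fit()
    _stage("fit", t1)
    if write:
        _write_bundle(config, model, results)
    return results


def _write_bundle(config: RunConfig, model: FrameComparison,
                  results: FrameComparisonResults) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "config": asdict(config)}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))

    margin_rows = [{"variable": m.variable, "category": c, "share": s}
                   for m in model.margins + model.external_margins
                   for c, s in zip(m.categories, m.shares)]
    pd.DataFrame(margin_rows).to_csv(out / "margins.csv", index=False)
    model.respondents.to_csv(out / "respondents.csv", index=False)
    if model.dispositions is not None:
        model.dispositions.to_csv(out / "dispositions.csv", index=False)
    if results.rates is not None:
        (out / "rates.json").write_text(json.dumps(
            {"rr3": results.rates.rr3,
             "eligibility_factor": results.rates.eligibility_factor}, indent=2))

    weight_rows = []
    for label, ws in results.design_weights.items():
        cal = results.calibrated[label].weights
        for idx, w in ws.weights.items():
            weight_rows.append({
                "respondent": int(idx), "design_label": label,
                "design_weight": float(w),
                "calibrated_weight": float(cal.loc[idx]),
            })
    pd.DataFrame(weight_rows).to_csv(out / "weights.csv", index=False)
    (out / "raking.json").write_text(json.dumps(
        {label: {"iterations": r.iterations, "converged": r.converged,
                 "max_relative_deviation": r.max_relative_deviation,
                 "population_total": r.population_total}
         for label, r in results.raking.items()}, indent=2))

    bal = pd.concat([rep.categories.assign(design=label)
                     for label, rep in results.balance.items()])
    bal.to_csv(out / "balance_design_weights.csv", index=False)
    if results.balance_external:
        bal_ext = pd.concat([rep.categories.assign(design=label)
                             for label, rep in results.balance_external.items()])
        bal_ext.to_csv(out / "balance_external.csv", index=False)
    if results.r_indicators:
        (out / "r_indicators.json").write_text(json.dumps(
            {label: {"R": r.r, "propensity_sd": r.propensity_sd,
                     "model": r.model_description}
             for label, r in results.r_indicators.items()}, indent=2))

    for scope, table in results.estimates.items():
        table.to_csv(out / f"estimates_{scope.replace('-', '_')}.csv")
    (out / "summary.md").write_text(
        f"```\n{results.summary()}\n```\n"
        f"\nconfig_hash: {config.config_hash()}  seed: {config.seed}\n")


def replicate_study(config: RunConfig, n_replicates: int | None = None
                    ) -> pd.DataFrame:
    """Monte-Carlo study of both designs' estimators on a fixed population.

    The population (and hence the synthetic truth) is generated once from the
    master seed; fieldwork, weighting, calibration and estimation are
    replicated with independent seeds. Returns one row per (design,
    indicator) with the mean estimate, empirical SE, bias against the
    population truth (cell-covered truth for SF) and the coverage of
    plus/minus 2 SE intervals.
    """
    if n_replicates is None:
        n_replicates = config.replicates
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")

    pop_seed, *field_seeds = spawn_seeds(config.seed, n_replicates + 1)
    pop_cfg = config.population_config(pop_seed)
    persons, households = generate_population(pop_cfg)
    frames = build_frames(persons, households, config.nonworking_rate_ll,
                          config.nonworking_rate_cell)
    margins = reference_margins(persons, config.calibration_variables)
    truth_all = {ind: float(persons[ind].mean()) for ind in config.indicators}
    truth_cell = {ind: float(persons.loc[persons["n_cell"] > 0, ind].mean())
                  for ind in config.indicators}

    records = []
    for rep, seed in enumerate(field_seeds):
        field_cfg = config.fieldwork_config(seed)
        respondents, _ = simulate_calls(frames, persons, field_cfg, pop_cfg)
        design = SampleDesign(field_cfg.n_landline, frames.N_ll,
                              field_cfg.n_cell, frames.N_cell)
        ws_df = df_weights(respondents, design)
        sf_resp, ws_sf = build_counterfactual_sf(respondents, design)
        for label, sample, ws in (("DF", respondents, ws_df),
                                  ("SF", sf_resp, ws_sf)):
            cal = rake(ws.weights, sample, margins,
                       population_total=float(len(persons)))
            table = estimate_table(sample, cal.weights, config.indicators)
            for ind in config.indicators:
                records.append({
                    "replicate": rep, "design": label, "indicator": ind,
                    "estimate": table.loc[ind, "prevalence"],
                    "se": table.loc[ind, "se"],
                })
    raw = pd.DataFrame(records)

    rows = []
    for (label, ind), sub in raw.groupby(["design", "indicator"]):
        truth = truth_all[ind] if label == "DF" else truth_cell[ind]
        est = sub["estimate"].to_numpy()
        cover = np.mean(np.abs(est - truth) <= 2 * sub["se"].to_numpy())
        rows.append({
            "design": label, "indicator": ind, "truth": truth,
            "mean_estimate": float(est.mean()),
            "empirical_se": float(est.std(ddof=1)) if len(est) > 1 else float("nan"),
            "bias": float(est.mean() - truth),
            "coverage_2se": float(cover),
            "n_replicates": len(est),
        })
    return pd.DataFrame(rows)
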