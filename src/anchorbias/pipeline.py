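"""End-to-end experiment runner.

``run_experiment`` executes one scenario through every requested design:
simulate (or reuse) the population, build the vaccinated target cohort,
anchor each comparator, extract windowed covariates on both sides, compute
standardized differences, count imbalanced covariates, and write all
artifacts plus a manifest. Every stochastic stage receives a seed derived
from the experiment seed, and the resolved configuration is written out so a
run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import balance as bal
from .cohorts import (
    CohortTable,
    MatchSpec,
    build_vaccinated_cohort,
    match_arbitrary_date,
    match_visit_date,
    restrict_to_matched,
    self_controlled_anchors,
)
from .config import ScenarioConfig, make_scenario, save_config
from .covariates import DEFAULT_WINDOWS, WindowSet, extract_covariates
from .io import write_cohort, write_population
from .simulate import PopulationDataset, generate_population

log = logging.getLogger("anchorbias")

DESIGNS = ("cohort_arbitrary_date", "cohort_visit", "self_prior_date", "self_prior_visit")
DesignName = Literal["cohort_arbitrary_date", "cohort_visit", "self_prior_date", "self_prior_visit"]


class ExperimentSpec(BaseModel):
    """Everything needed to run (and re-run) one experiment."""

    scenario: ScenarioConfig | str
    designs: list[DesignName] = Field(min_length=1)
    match_spec: MatchSpec = MatchSpec()
    threshold: float = Field(default=0.1, gt=0)
    output_dir: Path
    seed: int = 0
    self_control_window: tuple[int, int] = (180, 450)
    write_population_tables: bool = False
    population_formats: tuple[str, ...] = ("csv",)

    @field_validator("designs")
    @classmethod
    def _unique(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("designs must be unique")
        return v


def _stage_seeds(seed: int) -> dict[str, int]:
    """Derive independent sub-seeds (< 2**31) for each stochastic stage."""
    state = np.random.SeedSequence(seed).generate_state(4) & 0x7FFFFFFF
    return {
        "simulate": int(state[0]),
        "match": int(state[1]),
        "self_control": int(state[2]),
    }


def resolve_scenario(spec: ExperimentSpec) -> ScenarioConfig:
    """Preset name -> fully populated config seeded from the experiment seed;
    an explicit ScenarioConfig keeps its own seed."""
    if isinstance(spec.scenario, str):
        return make_scenario(spec.scenario, seed=_stage_seeds(spec.seed)["simulate"])
    return spec.scenario


def build_comparator(
    design: str,
    targets: CohortTable,
    data: PopulationDataset,
    match_spec: MatchSpec,
    self_control_window: tuple[int, int] = (180, 450),
    seed: int = 0,
) -> CohortTable:
    """Anchor one comparator cohort for a named design."""
    if design == "cohort_arbitrary_date":
        return match_arbitrary_date(targets, data, match_spec)
    if design == "cohort_visit":
        return match_visit_date(targets, data, match_spec)
    if design in ("self_prior_date", "self_prior_visit"):
        mode = "prior_date" if design == "self_prior_date" else "prior_visit"
        return self_controlled_anchors(
            targets, data, mode, window_days=self_control_window, seed=seed,
            lookback_required_days=match_spec.lookback_required_days,
        )
    raise ValueError(f"unknown design {design!r}")


def run_design(
    design: str,
    targets: CohortTable,
    data: PopulationDataset,
    spec: ExperimentSpec,
    windows: WindowSet = DEFAULT_WINDOWS,
) -> dict:
    """Comparator, both covariate summaries, balance, imbalance, scatter for
    one design (complete-pair analysis: unmatched targets are dropped)."""
    seeds = _stage_seeds(spec.seed)
    match_spec = spec.match_spec.model_copy(update={"seed": seeds["match"]})
    comparator = build_comparator(
        design, targets, data, match_spec, spec.self_control_window,
        seed=seeds["self_control"],
    )
    cases = restrict_to_matched(targets, comparator)
    log.info("design %s: %d targets retained, %d comparator rows",
             design, len(cases), len(comparator))
    summary_t = extract_covariates(cases, data, windows, cohort_id="vaccinated")
    summary_c = extract_covariates(comparator, data, windows,
                                   cohort_id=comparator.anchor_type)
    balance_table = bal.compare_cohorts(summary_t, summary_c)
    imbalance = bal.count_imbalanced(balance_table, spec.threshold)
    scatter = bal.export_scatter(summary_t, summary_c)
    return {
        "design": design,
        "comparator": comparator,
        "cases": cases,
        "summary_target": summary_t,
        "summary_comparator": summary_c,
        "balance": balance_table,
        "imbalance": imbalance,
        "scatter": scatter,
    }


def run_experiment(spec: ExperimentSpec, data: PopulationDataset | None = None) -> dict:
    """Run every design of ``spec`` and write artifacts under
    ``spec.output_dir``; returns the manifest (also written as JSON).

    ``data`` may be supplied to reuse an existing population (e.g. loaded
    from disk); otherwise it is generated from the resolved scenario.
    """
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(spec.seed)
    scenario = resolve_scenario(spec)
    save_config(scenario, out / "resolved_scenario.yaml")
    (out / "experiment.json").write_text(
        spec.model_copy(update={"scenario": scenario}).model_dump_json(indent=2)
    )

    if data is None:
        log.info("simulating population: n=%d seed=%d", scenario.n_persons, scenario.seed)
        data = generate_population(scenario)
    log.info("population: %d persons, %d visits, %d events, %d vaccinated",
             len(data.persons), len(data.visits), len(data.events),
             len(data.vaccinations))
    if spec.write_population_tables:
        write_population(data, out / "population", formats=spec.population_formats)

    match_spec = spec.match_spec.model_copy(update={"seed": seeds["match"]})
    targets = build_vaccinated_cohort(data, match_spec)
    write_cohort(targets, out / "target_cohort.csv", data.observation_start)

    manifest: dict = {
        "seed": spec.seed,
        "stage_seeds": seeds,
        "threshold": spec.threshold,
        "scenario_file": "resolved_scenario.yaml",
        "n_persons": len(data.persons),
        "n_vaccinated": int(len(data.vaccinations)),
        "n_targets": len(targets),
        "designs": {},
    }
    results: dict = {"targets": targets, "data": data, "designs": {}}
    for design in spec.designs:
        ddir = out / design
        ddir.mkdir(exist_ok=True)
        res = run_design(design, targets, data, spec)
        results["designs"][design] = res
        write_cohort(res["comparator"], ddir / "comparator_cohort.csv",
                     data.observation_start)
        for name in ("summary_target", "summary_comparator", "balance",
                     "imbalance", "scatter"):
            res[name].to_csv(ddir / f"{name}.csv", index=False)
        (ddir / "imbalance_table.md").write_text(
            bal.render_imbalance_table(res["imbalance"]) + "\n"
        )
        att = res["comparator"].attrition
        manifest["designs"][design] = {
            "n_cases": len(res["cases"]),
            "n_comparators": len(res["comparator"]),
            "attrition": att.to_dict("records"),
            "n_imbalanced": {
                r.window_name: int(r.n_imbalanced)
                for r in res["imbalance"].itertuples()
            },
            "n_covariates": int(res["imbalance"].n_total.iloc[0])
            if len(res["imbalance"]) else 0,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
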