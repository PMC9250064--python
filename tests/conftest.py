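"""Shared fixtures: hand-built micro datasets and session-scoped scenario runs."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from anchorbias import ExperimentSpec, PopulationDataset, ScenarioConfig, make_scenario
from anchorbias.pipeline import run_experiment

OBS_START = dt.date(2015, 1, 1)
OBS_END = dt.date(2017, 12, 31)  # 1096 days


def build_dataset(
    persons: list[tuple],
    visits: list[tuple],
    events: list[tuple],
    vaccinations: list[tuple],
    start: dt.date = OBS_START,
    end: dt.date = OBS_END,
) -> PopulationDataset:
    """Assemble a PopulationDataset from literal row tuples.

    persons: (person_id, sex, age, burden); visits: (person_id, day);
    events: (person_id, day, concept_id, domain);
    vaccinations: (person_id, day, coupled).
    """
    return PopulationDataset(
        persons=pd.DataFrame(
            persons, columns=["person_id", "sex", "age_at_start", "latent_burden"]
        ),
        visits=pd.DataFrame(visits, columns=["person_id", "visit_day"]),
        events=pd.DataFrame(
            events, columns=["person_id", "event_day", "concept_id", "domain"]
        ),
        vaccinations=pd.DataFrame(
            vaccinations, columns=["person_id", "vaccination_day", "coupled_flag"]
        ),
        observation_start=start,
        observation_end=end,
    )


def small_config(**overrides) -> ScenarioConfig:
    """A fast, fully explicit scenario for unit tests (not a preset)."""
    base = dict(
        n_persons=300,
        observation_start=OBS_START,
        observation_end=OBS_END,
        age_distribution={30: 0.5, 60: 0.5},
        sex_probability=0.5,
        health_burden_shape=2.0,
        health_burden_scale=0.5,
        n_chronic_concepts=3,
        n_acute_concepts=2,
        n_measurement_concepts=2,
        n_drug_concepts=2,
        chronic_prevalence_intercepts=[-1.0, -0.5, 0.0],
        burden_loadings=[0.5, 0.5, 0.5],
        age_loadings=[0.1, 0.1, 0.1],
        base_visit_rate_per_day=0.01,
        visit_rate_burden_coef=0.3,
        visit_rate_age_coef=0.1,
        record_prob_chronic=0.4,
        record_prob_measurement=0.3,
        record_prob_drug=0.2,
        acute_event_prob_per_visit=0.05,
        vaccination_logit_intercept=-0.5,
        vaccination_burden_coef=0.5,
        vaccination_age_coef=0.05,
        visit_coupling_prob=0.5,
        vaccination_window=(dt.date(2017, 6, 1), dt.date(2017, 8, 31)),
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


ALL_DESIGNS = [
    "cohort_arbitrary_date",
    "cohort_visit",
    "self_prior_date",
    "self_prior_visit",
]


def _run_scenario(preset: str, designs: list[str], tmp_path_factory, seed: int) -> dict:
    spec = ExperimentSpec(
        scenario=make_scenario(preset, n_persons=20_000, seed=seed),
        designs=designs,
        output_dir=tmp_path_factory.mktemp(preset),
        seed=seed,
    )
    return run_experiment(spec)


@pytest.fixture(scope="session")
def influenza_results(tmp_path_factory) -> dict:
    """Influenza-like regime at n=20,000: visit-coupled vaccination (kappa
    0.558) targeted to sicker patients; all four designs."""
    return _run_scenario("influenza_like", ALL_DESIGNS, tmp_path_factory, seed=11)


@pytest.fixture(scope="session")
def covid_results(tmp_path_factory) -> dict:
    """COVID-like regime at n=20,000: visit-decoupled vaccination (kappa
    0.027) reaching a healthier population; cohort designs."""
    return _run_scenario(
        "covid_like", ["cohort_arbitrary_date", "cohort_visit"], tmp_path_factory,
        seed=11,
    )
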