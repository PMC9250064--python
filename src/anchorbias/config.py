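"""Scenario configuration for the synthetic-EHR generator and its presets.

A :class:`ScenarioConfig` fully determines one simulated population: the
demographic mix, the latent health-burden distribution, the
utilization-dependent visit process, the encounter-conditional recording
probabilities, the health-selected vaccination model, and — the key dial —
the visit-coupling probability ``visit_coupling_prob``: the probability that
a vaccination is administered during a health care encounter.

Three presets bracket the designs of interest:

``influenza_like``
    Vaccination strongly coupled to visits (55.8% of influenza vaccinees in
    large EHR sources have a visit on the vaccination day) and targeted to
    sicker patients (positive burden coefficient in the vaccination model).
``covid_like``
    Vaccination almost decoupled from care (2.7% visit coupling, mass
    vaccination sites) and reaching a healthier-than-EHR-average population
    (negative burden coefficient).
``null``
    Vaccination assigned at random (no health selection) with coupling equal
    to the background daily visit probability, so the vaccination day looks
    like any other day up to a negligible residual; used for calibration.

All dates are handled internally as integer day offsets from
``observation_start``; exported tables use ISO-8601 calendar dates.
"""

from __future__ import annotations

import datetime as dt
import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

#: Baseline lookback (days) that every index date must admit.
LOOKBACK_DAYS = 450

#: Minimum observation-period length (days).
MIN_OBSERVATION_DAYS = 900

#: Concept-ID block offsets per concept class (simplified vocabulary:
#: small integers plus a domain column, no real OMOP concept mapping).
CONCEPT_ID_BASE = {"chronic": 1000, "acute": 2000, "measurement": 3000, "drug": 4000}

#: Domain recorded for each concept class.
CONCEPT_DOMAIN = {
    "chronic": "condition",
    "acute": "condition",
    "measurement": "measurement",
    "drug": "drug",
}

PresetName = Literal["influenza_like", "covid_like", "null"]


class ScenarioConfig(BaseModel):
    """All generator parameters for one synthetic population.

    Identical config + seed yields bit-identical output tables.
    """

    n_persons: int = Field(gt=0)
    observation_start: dt.date
    observation_end: dt.date
    #: categorical distribution over integer ages at observation_start
    age_distribution: dict[int, float]
    #: probability that a person is female
    sex_probability: float = Field(ge=0.0, le=1.0)

    # latent health burden h ~ Gamma(shape, scale), one draw per person
    health_burden_shape: float = Field(gt=0)
    health_burden_scale: float = Field(gt=0)

    # concept universe sizes
    n_chronic_concepts: int = Field(ge=0)
    n_acute_concepts: int = Field(ge=0)
    n_measurement_concepts: int = Field(ge=0)
    n_drug_concepts: int = Field(ge=0)

    # chronic-condition presence model: logistic(intercept_c + b_c*h + a_c*age_decades)
    chronic_prevalence_intercepts: list[float]
    burden_loadings: list[float]
    age_loadings: list[float]

    # visit process: per-day Poisson rate lambda0 * exp(b*h + a*age_decades)
    base_visit_rate_per_day: float = Field(gt=0)
    visit_rate_burden_coef: float
    visit_rate_age_coef: float

    # encounter-conditional recording probabilities
    record_prob_chronic: float = Field(ge=0.0, le=1.0)
    record_prob_measurement: float = Field(ge=0.0, le=1.0)
    record_prob_drug: float = Field(ge=0.0, le=1.0)
    acute_event_prob_per_visit: float = Field(ge=0.0, le=1.0)

    # vaccination model: logistic(intercept + b*h + a*age_decades)
    vaccination_logit_intercept: float
    vaccination_burden_coef: float
    vaccination_age_coef: float
    #: probability that the vaccination date is moved onto a visit
    visit_coupling_prob: float = Field(ge=0.0, le=1.0)
    vaccination_window: tuple[dt.date, dt.date]
    seed: int = 0

    @model_validator(mode="after")
    def _check_consistency(self) -> "ScenarioConfig":
        span = (self.observation_end - self.observation_start).days + 1
        if span < MIN_OBSERVATION_DAYS:
            raise ValueError(
                f"observation period spans {span} days; at least "
                f"{MIN_OBSERVATION_DAYS} are required"
            )
        w0, w1 = self.vaccination_window
        if w0 > w1:
            raise ValueError("vaccination_window start is after its end")
        if w0 < self.observation_start or w1 > self.observation_end:
            raise ValueError("vaccination_window must lie within the observation period")
        if (w0 - self.observation_start).days < LOOKBACK_DAYS:
            raise ValueError(
                f"every vaccination date must admit a {LOOKBACK_DAYS}-day lookback; "
                f"move vaccination_window at least {LOOKBACK_DAYS} days after "
                "observation_start"
            )
        probs = self.age_distribution
        if not probs:
            raise ValueError("age_distribution is empty")
        if any(p < 0 for p in probs.values()) or not math.isclose(
            sum(probs.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("age_distribution probabilities must be >=0 and sum to 1")
        for name in ("chronic_prevalence_intercepts", "burden_loadings", "age_loadings"):
            if len(getattr(self, name)) != self.n_chronic_concepts:
                raise ValueError(f"{name} must have length n_chronic_concepts")
        return self

    # ---- day-offset helpers -------------------------------------------------

    @property
    def n_days(self) -> int:
        """Observation-period length in days (inclusive of both endpoints)."""
        return (self.observation_end - self.observation_start).days + 1

    def day_of(self, date: dt.date) -> int:
        return (date - self.observation_start).days

    def date_of(self, day: int) -> dt.date:
        return self.observation_start + dt.timedelta(days=int(day))

    @property
    def vaccination_day_range(self) -> tuple[int, int]:
        w0, w1 = self.vaccination_window
        return self.day_of(w0), self.day_of(w1)

    def concept_ids(self, kind: str) -> range:
        n = {
            "chronic": self.n_chronic_concepts,
            "acute": self.n_acute_concepts,
            "measurement": self.n_measurement_concepts,
            "drug": self.n_drug_concepts,
        }[kind]
        base = CONCEPT_ID_BASE[kind]
        return range(base, base + n)

    @property
    def mean_age(self) -> float:
        return sum(a * p for a, p in self.age_distribution.items())

    @property
    def mean_burden(self) -> float:
        return self.health_burden_shape * self.health_burden_scale

    @property
    def background_daily_visit_prob(self) -> float:
        """Daily visit probability 1 - exp(-rate) at the population-mean
        burden and age (used to calibrate the null preset's coupling)."""
        rate = self.base_visit_rate_per_day * math.exp(
            self.visit_rate_burden_coef * self.mean_burden
            + self.visit_rate_age_coef * self.mean_age / 10.0
        )
        return 1.0 - math.exp(-rate)


def _uniform_age_distribution(lo: int = 18, hi: int = 84) -> dict[int, float]:
    ages = list(range(lo, hi + 1))
    p = 1.0 / len(ages)
    dist = {a: p for a in ages}
    # exact normalization despite float division
    dist[ages[-1]] += 1.0 - sum(dist.values())
    return dist


def make_scenario(
    preset: PresetName, n_persons: int = 20_000, seed: int = 0
) -> ScenarioConfig:
    """Return a fully populated :class:`ScenarioConfig` for a named preset.

    Parameters common to all presets: adult EHR-like population (ages 18-84),
    gamma(2, 0.5) latent burden (mean 1), ~6-7 visits/year at the mean,
    40/20/30/30 chronic/acute/measurement/drug concepts. Presets differ in
    the vaccination model (health selection) and visit coupling.
    """
    n_chronic = 40
    common = dict(
        n_persons=n_persons,
        age_distribution=_uniform_age_distribution(),
        health_burden_shape=2.0,
        health_burden_scale=0.5,
        n_chronic_concepts=n_chronic,
        n_acute_concepts=20,
        n_measurement_concepts=30,
        n_drug_concepts=30,
        chronic_prevalence_intercepts=[
            -4.0 + 3.0 * i / (n_chronic - 1) for i in range(n_chronic)
        ],
        burden_loadings=[0.6] * n_chronic,
        age_loadings=[0.15] * n_chronic,
        base_visit_rate_per_day=0.006,
        visit_rate_burden_coef=0.5,
        visit_rate_age_coef=0.12,
        record_prob_chronic=0.35,
        record_prob_measurement=0.20,
        record_prob_drug=0.15,
        acute_event_prob_per_visit=0.03,
        seed=seed,
    )
    if preset == "influenza_like":
        return ScenarioConfig(
            observation_start=dt.date(2015, 1, 1),
            observation_end=dt.date(2018, 6, 30),
            sex_probability=0.614,
            vaccination_logit_intercept=-1.8,
            vaccination_burden_coef=0.8,
            vaccination_age_coef=0.05,
            visit_coupling_prob=0.558,
            vaccination_window=(dt.date(2017, 9, 15), dt.date(2017, 12, 15)),
            **common,
        )
    if preset == "covid_like":
        return ScenarioConfig(
            observation_start=dt.date(2018, 6, 1),
            observation_end=dt.date(2021, 12, 31),
            sex_probability=0.627,
            vaccination_logit_intercept=-0.3,
            vaccination_burden_coef=-0.8,
            vaccination_age_coef=0.05,
            visit_coupling_prob=0.027,
            vaccination_window=(dt.date(2021, 1, 1), dt.date(2021, 6, 30)),
            **common,
        )
    if preset == "null":
        cfg = ScenarioConfig(
            observation_start=dt.date(2015, 1, 1),
            observation_end=dt.date(2018, 6, 30),
            sex_probability=0.5,
            vaccination_logit_intercept=-0.85,
            vaccination_burden_coef=0.0,
            vaccination_age_coef=0.0,
            visit_coupling_prob=0.0,  # placeholder, replaced below
            vaccination_window=(dt.date(2017, 9, 15), dt.date(2017, 12, 15)),
            **common,
        )
        return cfg.model_copy(
            update={"visit_coupling_prob": cfg.background_daily_visit_prob}
        )
    raise ValueError(f"unknown preset {preset!r}")


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a config to YAML (round-trippable via :func:`load_config`)."""
    data = config.model_dump(mode="python")
    data["vaccination_window"] = list(data["vaccination_window"])  # YAML has no tuple
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path: str | Path) -> ScenarioConfig:
    return ScenarioConfig.model_validate(yaml.safe_load(Path(path).read_text()))
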