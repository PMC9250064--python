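"""Mechanistic synthetic-EHR generator.

The generator produces an OMOP-lite longitudinal dataset in which the
*recording process is encounter-driven*: clinical facts enter the record only
when the patient has a visit. That single mechanism is what makes index-date
anchoring matter downstream — a cohort indexed on a visit mechanically has
day-0 records, a cohort indexed on an arbitrary date mostly does not.

Generative model, per person i:

1. demographics: age ~ configured categorical, sex ~ Bernoulli(p_female);
2. latent health burden h_i ~ Gamma(shape, scale) — never observable
   downstream, only through utilization and recorded facts;
3. chronic-condition presence: concept c present with probability
   logistic(intercept_c + burden_loading_c * h_i + age_loading_c * age_dec_i),
   where age_dec is age in decades;
4. visits: homogeneous Poisson process with per-day rate
   lambda0 * exp(b_v * h_i + a_v * age_dec_i); visit dates deduplicated;
5. recording at each visit: every *present* chronic concept with prob
   record_prob_chronic; every measurement concept with
   record_prob_measurement; every drug concept with record_prob_drug; every
   acute concept with acute_event_prob_per_visit (acute facts need no latent
   presence — they model self-limited complaints seen at encounters);
6. vaccination (first dose only): assigned with probability
   logistic(intercept + b_x * h_i + a_x * age_dec_i); date uniform over the
   vaccination window; with probability kappa (``visit_coupling_prob``) the
   date is *coupled* to a visit — moved to a uniformly chosen existing visit
   inside the window if the person has one, else a new visit is created on
   the sampled date. Uncoupled vaccinations leave the visit process alone,
   so they coincide with a visit only by chance.

All dates are integer day offsets from ``observation_start``; every person is
observed for the whole period.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CONCEPT_DOMAIN, CONCEPT_ID_BASE, ScenarioConfig

DOMAIN_CATEGORIES = ["condition", "procedure", "measurement", "drug"]


@dataclasses.dataclass
class PopulationDataset:
    """Linked person/visit/event/vaccination tables for one simulated cohort.

    Tables use integer day offsets from ``observation_start``:

    - ``persons``: person_id, sex ('F'/'M'), age_at_start, latent_burden
    - ``visits``: person_id, visit_day (unique per person-day)
    - ``events``: person_id, event_day, concept_id, domain
    - ``vaccinations``: person_id, vaccination_day, coupled_flag (at most one
      row per person)

    Invariants: every event_day coincides with a visit_day of the same
    person; every coupled vaccination has a same-person visit on its day.
    """

    persons: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    vaccinations: pd.DataFrame
    observation_start: dt.date
    observation_end: dt.date

    @property
    def n_days(self) -> int:
        return (self.observation_end - self.observation_start).days + 1

    def concept_universe(self) -> pd.DataFrame:
        """All concepts observed anywhere in the data, with their domain."""
        return (
            self.events[["concept_id", "domain"]]
            .drop_duplicates("concept_id")
            .sort_values("concept_id")
            .reset_index(drop=True)
        )


def _record_events(
    rng: np.random.Generator,
    visit_person: np.ndarray,
    visit_day: np.ndarray,
    concept_base: int,
    n_concepts: int,
    prob: float,
    presence: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli recording mask over visits x concepts -> event triples."""
    if n_concepts == 0 or len(visit_person) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    mask = rng.random((len(visit_person), n_concepts)) < prob
    if presence is not None:
        mask &= presence[visit_person]
    vi, ci = np.nonzero(mask)
    return visit_person[vi], visit_day[vi], (concept_base + ci).astype(np.int64)


def generate_population(config: ScenarioConfig) -> PopulationDataset:
    """Simulate one population under ``config`` (deterministic in its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    n_days = config.n_days

    # --- persons -------------------------------------------------------------
    ages_support = np.array(sorted(config.age_distribution), dtype=np.int64)
    age_probs = np.array([config.age_distribution[int(a)] for a in ages_support])
    age_probs = age_probs / age_probs.sum()
    ages = rng.choice(ages_support, size=n, p=age_probs)
    female = rng.random(n) < config.sex_probability
    burden = rng.gamma(config.health_burden_shape, config.health_burden_scale, size=n)
    age_dec = ages / 10.0

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "sex": np.where(female, "F", "M"),
            "age_at_start": ages,
            "latent_burden": burden,
        }
    )

    # --- chronic-condition presence -----------------------------------------
    nc = config.n_chronic_concepts
    if nc:
        logits = (
            np.asarray(config.chronic_prevalence_intercepts)[None, :]
            + burden[:, None] * np.asarray(config.burden_loadings)[None, :]
            + age_dec[:, None] * np.asarray(config.age_loadings)[None, :]
        )
        chronic_present = rng.random((n, nc)) < expit(logits)
    else:
        chronic_present = np.zeros((n, 0), dtype=bool)

    # --- visits (homogeneous Poisson, deduplicated days) ---------------------
    rate = config.base_visit_rate_per_day * np.exp(
        config.visit_rate_burden_coef * burden + config.visit_rate_age_coef * age_dec
    )
    n_visits = rng.poisson(rate * n_days)
    visit_person = np.repeat(np.arange(n, dtype=np.int64), n_visits)
    visit_day = rng.integers(0, n_days, size=int(n_visits.sum()), dtype=np.int64)
    visits = (
        pd.DataFrame({"person_id": visit_person, "visit_day": visit_day})
        .drop_duplicates()
        .sort_values(["person_id", "visit_day"])
        .reset_index(drop=True)
    )

    # --- vaccination assignment ----------------------------------------------
    p_vacc = expit(
        config.vaccination_logit_intercept
        + config.vaccination_burden_coef * burden
        + config.vaccination_age_coef * age_dec
    )
    vaccinated = np.nonzero(rng.random(n) < p_vacc)[0].astype(np.int64)
    w_lo, w_hi = config.vaccination_day_range
    vacc_day = rng.integers(w_lo, w_hi + 1, size=len(vaccinated), dtype=np.int64)
    coupled = rng.random(len(vaccinated)) < config.visit_coupling_prob

    # coupled vaccinations: move onto an existing in-window visit when one
    # exists (uniform choice), otherwise create a visit on the sampled date
    in_window = visits[(visits.visit_day >= w_lo) & (visits.visit_day <= w_hi)]
    window_visits = {
        pid: grp.to_numpy() for pid, grp in in_window.groupby("person_id")["visit_day"]
    }
    new_visit_rows: list[tuple[int, int]] = []
    for k in np.nonzero(coupled)[0]:  # ascending person order: deterministic
        pid = int(vaccinated[k])
        days = window_visits.get(pid)
        if days is not None and len(days):
            vacc_day[k] = days[rng.integers(0, len(days))]
        else:
            new_visit_rows.append((pid, int(vacc_day[k])))

    if new_visit_rows:
        visits = (
            pd.concat(
                [visits, pd.DataFrame(new_visit_rows, columns=["person_id", "visit_day"])]
            )
            .drop_duplicates()
            .sort_values(["person_id", "visit_day"])
            .reset_index(drop=True)
        )

    vaccinations = pd.DataFrame(
        {
            "person_id": vaccinated,
            "vaccination_day": vacc_day,
            "coupled_flag": coupled,
        }
    ).reset_index(drop=True)

    # --- encounter-conditional recording --------------------------------------
    vp = visits.person_id.to_numpy()
    vd = visits.visit_day.to_numpy()
    parts = []
    for kind, n_k, prob, presence in [
        ("chronic", nc, config.record_prob_chronic, chronic_present),
        ("acute", config.n_acute_concepts, config.acute_event_prob_per_visit, None),
        ("measurement", config.n_measurement_concepts, config.record_prob_measurement, None),
        ("drug", config.n_drug_concepts, config.record_prob_drug, None),
    ]:
        p_ids, days, cids = _record_events(
            rng, vp, vd, CONCEPT_ID_BASE[kind], n_k, prob, presence
        )
        parts.append(
            pd.DataFrame(
                {
                    "person_id": p_ids,
                    "event_day": days,
                    "concept_id": cids,
                    "domain": CONCEPT_DOMAIN[kind],
                }
            )
        )
    events = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["person_id", "event_day", "concept_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    events["domain"] = pd.Categorical(events["domain"], categories=DOMAIN_CATEGORIES)

    return PopulationDataset(
        persons=persons,
        visits=visits,
        events=events,
        vaccinations=vaccinations,
        observation_start=config.observation_start,
        observation_end=config.observation_end,
    )
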