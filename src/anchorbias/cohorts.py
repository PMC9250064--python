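"""Cohort construction: the vaccinated target and its anchored comparators.

Two families of comparison are supported, mirroring the cohort and
self-controlled (case-crossover) designs used in vaccine safety work:

- cohort design: unvaccinated comparators matched 1:1 (by default) to
  vaccinated targets on sex, age bin and calendar date, indexed either on an
  *arbitrary date* (the target's index date, no encounter required) or on a
  *visit* occurring that day;
- self-controlled design: the vaccinated persons serve as their own
  controls, re-indexed on an arbitrary prior day (``prior_date``) or a prior
  visit (``prior_visit``) 180-450 days before vaccination.

Matching is greedy in a seed-shuffled target order, exact on (sex, age bin,
calendar date); unmatched targets are dropped from the comparison and
reported in the attrition table, never silently.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .config import LOOKBACK_DAYS
from .simulate import PopulationDataset

AnchorType = Literal[
    "vaccination", "matched_date", "matched_visit", "prior_date", "prior_visit"
]

COHORT_COLUMNS = ["person_id", "index_day", "anchor_type", "match_group_id"]
ATTRITION_COLUMNS = ["stage", "n_in", "n_selected", "n_excluded", "reason"]


class MatchSpec(BaseModel):
    """Exact-matching specification for the cohort-design comparators."""

    age_bin_width: int = Field(default=5, ge=1)
    require_same_sex: bool = True
    require_same_calendar_date: bool = True
    ratio: int = Field(default=1, ge=1)
    with_replacement: bool = False
    lookback_required_days: int = Field(default=LOOKBACK_DAYS, ge=0)
    #: visit-date matching tolerance in days (0 = strict same-day)
    visit_day_tolerance: int = Field(default=0, ge=0)
    seed: int = 0


@dataclasses.dataclass
class CohortTable:
    """(person, index day, anchor type, match group) rows plus attrition.

    ``match_group_id`` links a comparator/control row to its target/case row;
    for target cohorts it simply identifies the row itself.
    """

    table: pd.DataFrame
    attrition: pd.DataFrame
    anchor_type: str
    #: with-replacement matching may reuse a comparator person across targets
    allow_duplicate_persons: bool = False

    def __post_init__(self) -> None:
        self.table = self.table[COHORT_COLUMNS].reset_index(drop=True)
        if not self.allow_duplicate_persons and self.table.person_id.duplicated().any():
            raise ValueError("person_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.table)


def _attrition_row(stage: str, n_in: int, n_selected: int, reason: str) -> dict:
    return {
        "stage": stage,
        "n_in": n_in,
        "n_selected": n_selected,
        "n_excluded": n_in - n_selected,
        "reason": reason,
    }


def _empty_cohort(anchor_type: str, attrition_rows: list[dict]) -> CohortTable:
    return CohortTable(
        table=pd.DataFrame(columns=COHORT_COLUMNS).astype(
            {"person_id": np.int64, "index_day": np.int64, "match_group_id": np.int64,
             "anchor_type": object}
        ),
        attrition=pd.DataFrame(attrition_rows, columns=ATTRITION_COLUMNS),
        anchor_type=anchor_type,
    )


def build_vaccinated_cohort(
    data: PopulationDataset, spec: MatchSpec | None = None
) -> CohortTable:
    """Vaccination-anchored target cohort: one row per vaccinated person whose
    vaccination date admits the required lookback."""
    spec = spec or MatchSpec()
    vacc = data.vaccinations
    eligible = vacc[vacc.vaccination_day >= spec.lookback_required_days]
    rows = [_attrition_row(
        "vaccinated_lookback", len(vacc), len(eligible),
        f"requires >= {spec.lookback_required_days} days of prior observation",
    )]
    if len(vacc) == 0:
        warnings.warn("no vaccinated persons in the dataset; empty target cohort")
    table = pd.DataFrame(
        {
            "person_id": eligible.person_id.to_numpy(np.int64),
            "index_day": eligible.vaccination_day.to_numpy(np.int64),
            "anchor_type": "vaccination",
            "match_group_id": eligible.person_id.to_numpy(np.int64),
        }
    ).sort_values("person_id").reset_index(drop=True)
    return CohortTable(
        table=table,
        attrition=pd.DataFrame(rows, columns=ATTRITION_COLUMNS),
        anchor_type="vaccination",
    )


def _age_bins(data: PopulationDataset, width: int) -> pd.Series:
    return (data.persons.set_index("person_id").age_at_start // width).astype(int)


def _unvaccinated_ids(data: PopulationDataset) -> np.ndarray:
    all_ids = data.persons.person_id.to_numpy(np.int64)
    return np.setdiff1d(all_ids, data.vaccinations.person_id.to_numpy(np.int64))


def _match_greedy(
    targets: CohortTable,
    data: PopulationDataset,
    spec: MatchSpec,
    anchor_type: str,
    candidate_index: dict,
    pick_index_day,
    stage: str,
) -> CohortTable:
    """Greedy exact matching common to the arbitrary-date and visit variants.

    ``candidate_index`` maps a stratum key to a seed-shuffled candidate list;
    ``pick_index_day(candidate, target_day)`` returns the comparator's index
    day or None if the candidate is not usable for this target.
    """
    rng = np.random.default_rng(spec.seed)
    tdf = targets.table.sort_values("person_id").reset_index(drop=True)
    order = rng.permutation(len(tdf))

    sex = data.persons.set_index("person_id").sex
    bins = _age_bins(data, spec.age_bin_width)

    used: set[int] = set()
    out_rows: list[tuple[int, int, int]] = []
    n_unmatched = 0
    for pos in order:
        t = tdf.iloc[pos]
        key = (
            sex.at[t.person_id] if spec.require_same_sex else "*",
            int(bins.at[t.person_id]),
        )
        pool = candidate_index.get(key, [])
        found = 0
        for cand in pool:
            if found >= spec.ratio:
                break
            if not spec.with_replacement and cand in used:
                continue
            if spec.with_replacement and any(
                r[0] == cand and r[2] == t.match_group_id for r in out_rows
            ):
                continue  # never pair the same candidate twice with one target
            day = pick_index_day(cand, int(t.index_day))
            if day is None:
                continue
            out_rows.append((cand, day, int(t.match_group_id)))
            if not spec.with_replacement:
                used.add(cand)
            found += 1
        if found < spec.ratio:
            n_unmatched += 1

    attrition = list(targets.attrition.to_dict("records"))
    attrition.append(
        _attrition_row(stage, len(tdf), len(tdf) - n_unmatched,
                       "no eligible comparator in (sex, age bin, date) stratum")
    )
    if not out_rows:
        return _empty_cohort(anchor_type, attrition)
    table = (
        pd.DataFrame(out_rows, columns=["person_id", "index_day", "match_group_id"])
        .assign(anchor_type=anchor_type)
        .sort_values("person_id")
        .reset_index(drop=True)
    )
    return CohortTable(
        table=table,
        attrition=pd.DataFrame(attrition, columns=ATTRITION_COLUMNS),
        anchor_type=anchor_type,
        allow_duplicate_persons=spec.with_replacement,
    )


def _build_candidate_index(
    data: PopulationDataset, spec: MatchSpec, rng: np.random.Generator
) -> dict:
    """Stratum -> shuffled list of unvaccinated candidate person_ids."""
    sex = data.persons.set_index("person_id").sex
    bins = _age_bins(data, spec.age_bin_width)
    index: dict[tuple, list[int]] = {}
    for pid in _unvaccinated_ids(data):
        key = (sex.at[pid] if spec.require_same_sex else "*", int(bins.at[pid]))
        index.setdefault(key, []).append(int(pid))
    for key in sorted(index, key=str):
        rng.shuffle(index[key])
    return index


def match_arbitrary_date(
    targets: CohortTable, data: PopulationDataset, spec: MatchSpec | None = None
) -> CohortTable:
    """Comparators anchored on an *arbitrary date*: the target's index date,
    with no requirement of any medical event that day."""
    spec = spec or MatchSpec()
    rng = np.random.default_rng(spec.seed)
    candidate_index = _build_candidate_index(data, spec, rng)
    last_day = data.n_days - 1

    def pick(cand: int, target_day: int):
        if spec.require_same_calendar_date:
            day = target_day
        else:
            day = int(rng.integers(spec.lookback_required_days, last_day + 1))
        if day < spec.lookback_required_days or day > last_day:
            return None
        return day

    return _match_greedy(
        targets, data, spec, "matched_date", candidate_index, pick,
        stage="match_arbitrary_date",
    )


def match_visit_date(
    targets: CohortTable, data: PopulationDataset, spec: MatchSpec | None = None
) -> CohortTable:
    """Comparators anchored on a *visit* on the target's index date (strict
    same-day unless ``spec.visit_day_tolerance`` allows +/- d days; the
    comparator is indexed on the visit date itself)."""
    spec = spec or MatchSpec()
    rng = np.random.default_rng(spec.seed)
    candidate_index = _build_candidate_index(data, spec, rng)
    last_day = data.n_days - 1
    visit_days = {
        pid: set(grp) for pid, grp in data.visits.groupby("person_id")["visit_day"]
    }
    # nearest visit first; on ties the earlier day
    offsets = [0]
    for d in range(1, spec.visit_day_tolerance + 1):
        offsets.extend([-d, d])

    def pick(cand: int, target_day: int):
        days = visit_days.get(cand)
        if not days:
            return None
        if not spec.require_same_calendar_date:
            ok = sorted(
                d for d in days if spec.lookback_required_days <= d <= last_day
            )
            return ok[int(rng.integers(0, len(ok)))] if ok else None
        for off in offsets:
            day = target_day + off
            if day in days and spec.lookback_required_days <= day <= last_day:
                return day
        return None

    return _match_greedy(
        targets, data, spec, "matched_visit", candidate_index, pick,
        stage="match_visit_date",
    )


def self_controlled_anchors(
    targets: CohortTable,
    data: PopulationDataset,
    mode: Literal["prior_date", "prior_visit"],
    window_days: tuple[int, int] = (180, 450),
    seed: int = 0,
    lookback_required_days: int = LOOKBACK_DAYS,
) -> CohortTable:
    """Control rows for the self-controlled design: the *same* persons
    re-indexed on a uniformly sampled eligible day (``prior_date``) or visit
    day (``prior_visit``) in [index - window_days[1], index - window_days[0]].

    The control index must itself admit the configured lookback; persons with
    no eligible day are excluded from the design (the caller drops them from
    the case side too — use the returned cohort's person set).

    Sampling contract (stable for reproduction): one ``default_rng(seed)``,
    targets visited in ascending person_id order, one uniform draw per
    eligible person.
    """
    if mode not in ("prior_date", "prior_visit"):
        raise ValueError(f"unknown mode {mode!r}")
    if targets.anchor_type != "vaccination":
        raise ValueError("self-controlled anchors require a vaccination-anchored target")
    near, far = window_days
    rng = np.random.default_rng(seed)
    visit_days = {
        pid: np.sort(grp.to_numpy())
        for pid, grp in data.visits.groupby("person_id")["visit_day"]
    }
    rows = []
    tdf = targets.table.sort_values("person_id")
    for t in tdf.itertuples():
        lo = max(int(t.index_day) - far, lookback_required_days)
        hi = int(t.index_day) - near
        if hi < lo:
            continue
        if mode == "prior_date":
            day = int(lo + rng.integers(0, hi - lo + 1))
        else:
            days = visit_days.get(int(t.person_id))
            if days is None:
                continue
            eligible = days[(days >= lo) & (days <= hi)]
            if len(eligible) == 0:
                continue
            day = int(eligible[rng.integers(0, len(eligible))])
        rows.append((int(t.person_id), day, int(t.match_group_id)))

    attrition = list(targets.attrition.to_dict("records"))
    attrition.append(
        _attrition_row(
            f"self_controlled_{mode}", len(tdf), len(rows),
            f"no eligible {'day' if mode == 'prior_date' else 'visit'} in "
            f"[-{far}, -{near}] days with full lookback",
        )
    )
    if not rows:
        return _empty_cohort(mode, attrition)
    table = (
        pd.DataFrame(rows, columns=["person_id", "index_day", "match_group_id"])
        .assign(anchor_type=mode)
        .reset_index(drop=True)
    )
    return CohortTable(
        table=table,
        attrition=pd.DataFrame(attrition, columns=ATTRITION_COLUMNS),
        anchor_type=mode,
    )


def restrict_to_matched(targets: CohortTable, comparators: CohortTable) -> CohortTable:
    """Complete-pair analysis: keep only targets whose match group appears in
    the comparator cohort (unmatched targets were already counted in the
    comparator's attrition)."""
    keep = targets.table.match_group_id.isin(set(comparators.table.match_group_id))
    return CohortTable(
        table=targets.table[keep].reset_index(drop=True),
        attrition=targets.attrition,
        anchor_type=targets.anchor_type,
    )
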