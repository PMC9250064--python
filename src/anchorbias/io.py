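"""Flat-table import/export.

Population tables are written as CSV and/or Parquet with ISO-8601 calendar
dates; in memory the package works with integer day offsets from the
observation start, so conversion happens only at the boundary. A small
``meta.json`` records the observation period so datasets round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import DOMAIN_CATEGORIES, PopulationDataset

_DAY_COLUMNS = {"visit_day", "event_day", "vaccination_day", "index_day"}


def _days_to_dates(df: pd.DataFrame, start) -> pd.DataFrame:
    out = df.copy()
    origin = pd.Timestamp(start)
    for col in list(out.columns):
        if col in _DAY_COLUMNS:
            out[col] = (origin + pd.to_timedelta(out[col], unit="D")).dt.date
    return out.rename(columns={c: c.replace("_day", "_date") for c in _DAY_COLUMNS})


def _dates_to_days(df: pd.DataFrame, start) -> pd.DataFrame:
    out = df.copy()
    origin = pd.Timestamp(start)
    for col in list(out.columns):
        if col.endswith("_date"):
            out[col] = (pd.to_datetime(out[col]) - origin).dt.days.astype("int64")
    return out.rename(
        columns={c: c.replace("_date", "_day") for c in out.columns if c.endswith("_date")}
    )


def write_population(
    data: PopulationDataset, directory: str | Path, formats: tuple[str, ...] = ("csv",)
) -> None:
    """Write persons/visits/events/vaccinations (+ meta.json).

    ``formats`` is any subset of {"csv", "parquet"}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "persons": data.persons,
        "visits": data.visits,
        "events": data.events,
        "vaccinations": data.vaccinations,
    }
    for name, df in tables.items():
        exported = _days_to_dates(df, data.observation_start)
        for fmt in formats:
            if fmt == "csv":
                exported.to_csv(directory / f"{name}.csv", index=False)
            elif fmt == "parquet":
                exported.to_parquet(directory / f"{name}.parquet", index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")
    (directory / "meta.json").write_text(
        json.dumps(
            {
                "observation_start": data.observation_start.isoformat(),
                "observation_end": data.observation_end.isoformat(),
            },
            indent=2,
        )
    )


def read_population(directory: str | Path, fmt: str = "csv") -> PopulationDataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    start = pd.Timestamp(meta["observation_start"]).date()
    end = pd.Timestamp(meta["observation_end"]).date()

    def load(name: str) -> pd.DataFrame:
        if fmt == "csv":
            df = pd.read_csv(directory / f"{name}.csv")
        elif fmt == "parquet":
            df = pd.read_parquet(directory / f"{name}.parquet")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        return _dates_to_days(df, start)

    events = load("events")
    events["domain"] = pd.Categorical(events["domain"], categories=DOMAIN_CATEGORIES)
    vacc = load("vaccinations")
    vacc["coupled_flag"] = vacc["coupled_flag"].astype(bool)
    return PopulationDataset(
        persons=load("persons"),
        visits=load("visits"),
        events=events,
        vaccinations=vacc,
        observation_start=start,
        observation_end=end,
    )


def write_cohort(cohort, path: str | Path, observation_start) -> None:
    """CohortTable -> flat CSV with calendar index dates; attrition alongside."""
    path = Path(path)
    _days_to_dates(cohort.table, observation_start).to_csv(path, index=False)
    cohort.attrition.to_csv(path.with_name(path.stem + "_attrition.csv"), index=False)
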