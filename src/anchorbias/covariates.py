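"""Windowed baseline-covariate extraction.

Covariates are extracted over five closed day intervals relative to each
person's index date: the index day itself (day 0), the day before (day -1),
and short/medium/long lookback windows [-30, -1], [-180, -31], [-450, -181].
Day -1 is deliberately a sub-interval of the short window: each window is an
independent extraction, not a cell of a partition.

Binary covariates are patient proportions — the fraction of the cohort with
at least one record of a concept in the window (events deduplicated within
person x concept x window) — with SD sqrt(p(1-p)). The continuous covariate
is the per-person visit count in the window (mean, sample SD). Every concept
observed anywhere in the dataset appears in every summary, so two cohorts
from the same dataset always share one covariate universe.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohorts import CohortTable
from .simulate import PopulationDataset

#: continuous covariate identifier
VISIT_COUNT_ID = "visit_count"

SUMMARY_COLUMNS = [
    "cohort_id", "window_name", "covariate_id", "covariate_kind",
    "n_persons", "statistic", "dispersion",
]


@dataclasses.dataclass(frozen=True)
class WindowSet:
    """Named closed intervals [lo, hi] in days relative to the index date."""

    windows: tuple[tuple[str, int, int], ...]

    @classmethod
    def default(cls) -> "WindowSet":
        return cls(
            windows=(
                ("day0", 0, 0),
                ("day_minus1", -1, -1),
                ("short", -30, -1),
                ("medium", -180, -31),
                ("long", -450, -181),
            )
        )

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.windows]

    def assign(self, offset: int) -> set[str]:
        """Every window whose interval contains ``offset`` (possibly none,
        possibly two: day -1 belongs to both day_minus1 and short)."""
        return {name for name, lo, hi in self.windows if lo <= offset <= hi}


DEFAULT_WINDOWS = WindowSet.default()


def assign_window(event_day_offset: int, windows: WindowSet | None = None) -> set[str]:
    """Window membership of an offset = event_day - index_day."""
    return (windows or DEFAULT_WINDOWS).assign(int(event_day_offset))


def extract_covariates(
    cohort: CohortTable,
    data: PopulationDataset,
    windows: WindowSet | None = None,
    cohort_id: str | None = None,
) -> pd.DataFrame:
    """Per-window covariate summary (long format) for one cohort.

    ``n_persons`` equals the cohort size for every covariate: a concept never
    recorded in-window counts as 0 for that person, not as missing.
    """
    windows = windows or DEFAULT_WINDOWS
    cohort_id = cohort_id if cohort_id is not None else cohort.anchor_type
    universe = data.concept_universe()
    cdf = cohort.table
    n = len(cdf)
    if n == 0:
        warnings.warn(f"empty cohort {cohort_id!r}; empty covariate summary")
        return pd.DataFrame(columns=SUMMARY_COLUMNS)

    # cohort rows keyed by person; with-replacement cohorts may repeat a
    # person, in which case each row contributes separately
    idx = cdf[["person_id", "index_day"]].reset_index().rename(columns={"index": "row"})
    ev = data.events.merge(idx, on="person_id", how="inner")
    ev["offset"] = ev.event_day - ev.index_day
    vis = data.visits.merge(idx, on="person_id", how="inner")
    vis["offset"] = vis.visit_day - vis.index_day

    out = []
    for name, lo, hi in windows.windows:
        inw = ev[(ev.offset >= lo) & (ev.offset <= hi)]
        counts = (
            inw.drop_duplicates(["row", "concept_id"])
            .groupby("concept_id", observed=True)
            .size()
            .reindex(universe.concept_id, fill_value=0)
        )
        p = counts.to_numpy() / n
        out.append(
            pd.DataFrame(
                {
                    "cohort_id": cohort_id,
                    "window_name": name,
                    "covariate_id": universe.concept_id.astype(str).to_numpy(),
                    "covariate_kind": "binary",
                    "n_persons": n,
                    "statistic": p,
                    "dispersion": np.sqrt(p * (1.0 - p)),
                }
            )
        )
        vcounts = (
            vis[(vis.offset >= lo) & (vis.offset <= hi)]
            .groupby("row")
            .size()
            .reindex(range(n), fill_value=0)
            .to_numpy(dtype=float)
        )
        out.append(
            pd.DataFrame(
                {
                    "cohort_id": [cohort_id],
                    "window_name": [name],
                    "covariate_id": [VISIT_COUNT_ID],
                    "covariate_kind": ["continuous"],
                    "n_persons": [n],
                    "statistic": [vcounts.mean()],
                    "dispersion": [vcounts.std(ddof=1) if n > 1 else 0.0],
                }
            )
        )
    return pd.concat(out, ignore_index=True)[SUMMARY_COLUMNS]
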