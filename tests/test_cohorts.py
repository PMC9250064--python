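"""Cohort construction and anchored matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from anchorbias import (
    MatchSpec,
    build_vaccinated_cohort,
    generate_population,
    match_arbitrary_date,
    match_visit_date,
    restrict_to_matched,
    self_controlled_anchors,
)

from conftest import build_dataset, small_config


def person(pid, sex="F", age=50, burden=1.0):
    return (pid, sex, age, burden)


class TestVaccinatedCohort:
    def test_toy_cohort_size(self):
        """5 persons, 3 vaccinated late enough for the 450-day lookback."""
        data = build_dataset(
            persons=[person(i) for i in range(5)],
            visits=[(0, 500), (1, 510), (2, 520)],
            events=[],
            vaccinations=[(0, 500, True), (1, 510, True), (2, 520, True)],
        )
        cohort = build_vaccinated_cohort(data)
        assert len(cohort) == 3
        assert (cohort.table.anchor_type == "vaccination").all()
        assert cohort.attrition.n_excluded.sum() == 0

    def test_insufficient_lookback_excluded_and_counted(self):
        data = build_dataset(
            persons=[person(0), person(1)],
            visits=[],
            events=[],
            vaccinations=[(0, 500, False), (1, 100, False)],
        )
        cohort = build_vaccinated_cohort(data)
        assert cohort.table.person_id.tolist() == [0]
        stage = cohort.attrition.iloc[0]
        assert stage.n_excluded == 1

    def test_no_vaccinated_persons_warns(self):
        data = build_dataset(
            persons=[person(0)], visits=[], events=[], vaccinations=[]
        )
        with pytest.warns(UserWarning, match="no vaccinated"):
            cohort = build_vaccinated_cohort(data)
        assert len(cohort) == 0


class TestArbitraryDateMatching:
    def test_unique_feasible_assignment_is_found(self):
        """3 targets, 4 candidates; each target has exactly one stratum-
        compatible candidate, so greedy matching must equal the unique
        feasible assignment regardless of shuffle order."""
        data = build_dataset(
            persons=[
                person(0, "F", 50),  # targets
                person(1, "M", 50),
                person(2, "F", 71),
                person(3, "F", 52),  # the only (F, bin 10) candidate
                person(4, "M", 53),  # the only (M, bin 10) candidate
                person(5, "F", 74),  # the only (F, bin 14) candidate
                person(6, "M", 30),  # no matching target
            ],
            visits=[],
            events=[],
            vaccinations=[(0, 500, False), (1, 510, False), (2, 520, False)],
        )
        targets = build_vaccinated_cohort(data)
        matched = match_arbitrary_date(targets, data, MatchSpec(seed=5))
        expected = {0: 3, 1: 4, 2: 5}  # target -> its unique candidate
        got = dict(zip(matched.table.match_group_id, matched.table.person_id))
        assert got == expected
        # comparator indexed on the target's calendar date
        tidx = targets.table.set_index("match_group_id").index_day
        for row in matched.table.itertuples():
            assert row.index_day == tidx.at[row.match_group_id]
        assert matched.attrition.iloc[-1].n_excluded == 0

    def test_empty_stratum_leaves_target_unmatched(self):
        data = build_dataset(
            persons=[person(0, "F", 50), person(1, "M", 50)],
            visits=[],
            events=[],
            vaccinations=[(0, 500, False)],
        )
        targets = build_vaccinated_cohort(data)
        matched = match_arbitrary_date(targets, data, MatchSpec(seed=1))
        assert len(matched) == 0
        assert matched.attrition.iloc[-1].n_excluded == 1

    def test_no_reuse_without_replacement(self):
        """Two targets, one shared candidate: exactly one can be matched."""
        data = build_dataset(
            persons=[person(0), person(1), person(2)],
            visits=[],
            events=[],
            vaccinations=[(0, 500, False), (1, 510, False)],
        )
        targets = build_vaccinated_cohort(data)
        matched = match_arbitrary_date(targets, data, MatchSpec(seed=2))
        assert len(matched) == 1
        assert matched.attrition.iloc[-1].n_excluded == 1

    def test_replacement_allows_reuse(self):
        data = build_dataset(
            persons=[person(0), person(1), person(2)],
            visits=[],
            events=[],
            vaccinations=[(0, 500, False), (1, 510, False)],
        )
        targets = build_vaccinated_cohort(data)
        matched = match_arbitrary_date(
            targets, data, MatchSpec(seed=2, with_replacement=True)
        )
        assert len(matched.table) == 2
        assert set(matched.table.person_id) == {2}


class TestVisitDateMatching:
    def _data(self, visit_day):
        return build_dataset(
            persons=[person(0), person(1)],
            visits=[(1, visit_day)],
            events=[],
            vaccinations=[(0, 500, False)],
        )

    def test_same_day_visit_matches(self):
        targets = build_vaccinated_cohort(self._data(500))
        matched = match_visit_date(targets, self._data(500), MatchSpec(seed=0))
        assert matched.table.person_id.tolist() == [1]
        assert matched.table.index_day.tolist() == [500]

    def test_strict_mode_requires_same_day(self):
        data = self._data(503)
        targets = build_vaccinated_cohort(data)
        matched = match_visit_date(targets, data, MatchSpec(seed=0))
        assert len(matched) == 0

    def test_tolerance_matches_at_the_visit_date(self):
        """Tolerance +/-7: a visit 3 days after the index is used and the
        comparator is indexed on the visit date itself."""
        data = self._data(503)
        targets = build_vaccinated_cohort(data)
        matched = match_visit_date(
            targets, data, MatchSpec(seed=0, visit_day_tolerance=7)
        )
        assert matched.table.index_day.tolist() == [503]


class TestSelfControlled:
    def test_single_in_window_visit_is_forced(self):
        data = build_dataset(
            persons=[person(0)],
            visits=[(0, 700), (0, 980)],  # 980 is outside [-450, -180]
            events=[],
            vaccinations=[(0, 1000, True)],
        )
        targets = build_vaccinated_cohort(data)
        controls = self_controlled_anchors(targets, data, "prior_visit", seed=3)
        assert controls.table.index_day.tolist() == [700]
        assert controls.table.anchor_type.tolist() == ["prior_visit"]

    def test_person_without_in_window_visit_is_excluded(self):
        data = build_dataset(
            persons=[person(0)],
            visits=[(0, 980)],
            events=[],
            vaccinations=[(0, 1000, False)],
        )
        targets = build_vaccinated_cohort(data)
        controls = self_controlled_anchors(targets, data, "prior_visit", seed=3)
        assert len(controls) == 0
        assert controls.attrition.iloc[-1].n_excluded == 1
        # the case side is dropped symmetrically
        assert len(restrict_to_matched(targets, controls)) == 0

    def test_prior_date_sampler_matches_reference_implementation(self):
        """The prior_date draw follows a documented contract: one
        default_rng(seed), targets in ascending person order, one uniform
        integer draw over the eligible range per person."""
        vacc = [(0, 1000, False), (1, 950, False), (2, 1060, False)]
        data = build_dataset(
            persons=[person(i) for i in range(3)],
            visits=[],
            events=[],
            vaccinations=vacc,
        )
        targets = build_vaccinated_cohort(data)
        seed = 17
        controls = self_controlled_anchors(targets, data, "prior_date", seed=seed)

        rng = np.random.default_rng(seed)
        expected = {}
        for pid, vday, _ in sorted(vacc):
            lo, hi = max(vday - 450, 450), vday - 180
            expected[pid] = lo + int(rng.integers(0, hi - lo + 1))
        got = dict(zip(controls.table.person_id, controls.table.index_day))
        assert got == expected

    def test_control_offsets_within_window(self):
        data = generate_population(small_config(n_persons=400, seed=10))
        targets = build_vaccinated_cohort(data)
        for mode in ("prior_date", "prior_visit"):
            controls = self_controlled_anchors(targets, data, mode, seed=1)
            vacc = targets.table.set_index("person_id").index_day
            offsets = controls.table.index_day - vacc.loc[controls.table.person_id].to_numpy()
            assert ((offsets >= -450) & (offsets <= -180)).all()


def test_matched_marginals_equal_targets(seed=0):
    """On matched pairs the comparator sex and age-bin distributions equal
    the targets' exactly, and no comparator person is used twice."""
    data = generate_population(small_config(n_persons=800, seed=seed))
    targets = build_vaccinated_cohort(data)
    spec = MatchSpec(seed=seed)
    for matcher in (match_arbitrary_date, match_visit_date):
        matched = matcher(targets, data, spec)
        assert not matched.table.person_id.duplicated().any()
        cases = restrict_to_matched(targets, matched)
        demo = data.persons.set_index("person_id")
        for cohort in (cases, matched):
            assert len(cohort) == len(cases)

        def marginals(cohort):
            d = demo.loc[cohort.table.person_id]
            return (
                d.sex.value_counts().to_dict(),
                (d.age_at_start // spec.age_bin_width).value_counts().to_dict(),
            )

        assert marginals(cases) == marginals(matched)
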