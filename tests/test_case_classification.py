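"""Exclusion rules, deduplication and the case/non-case partition."""

from __future__ import annotations

import itertools
from datetime import date

import pytest

from otosignal import (
    CaseDefinition,
    SyntheticConfig,
    apply_exclusions,
    classify,
    deduplicate,
    default_case_definition,
    event_group_membership,
    generate,
    partition,
    DEFAULT_EVENT_GROUPS,
)
from otosignal.case_classification import DEFAULT_DEDUP_KEY, _dedup_key
from otosignal.errors import ConfigurationError

from conftest import make_db, make_report


def test_case_definition_rejects_overlapping_drop_pts():
    with pytest.raises(ConfigurationError):
        CaseDefinition(case_pts=frozenset({"tinnitus", "vertigo"}))


def test_default_case_definition_excludes_bare_vertigo_from_case_pts():
    cd = default_case_definition()
    assert "vertigo" not in cd.case_pts
    assert "vertigo positional" in cd.case_pts
    assert len(cd.case_pts) == 21


class TestDeduplicate:
    def test_later_duplicate_removed(self):
        a = make_report("A", receipt_date=date(2010, 1, 1))
        b = make_report("B", receipt_date=date(2010, 2, 1))
        db2, removed = deduplicate(make_db([a, b]))
        assert removed == ["B"]
        assert db2.report_ids == ["A"]

    def test_reports_differing_in_one_pt_both_retained(self):
        a = make_report("A", pts=("nausea",))
        b = make_report("B", pts=("nausea", "rash"))
        db2, removed = deduplicate(make_db([a, b]))
        assert removed == []
        assert len(db2) == 2

    def test_matches_brute_force_pairwise_oracle(self):
        # 5 reports containing 2 duplicate pairs -> 3 retained
        reports = [
            make_report("A", age=30, receipt_date=date(2010, 1, 1)),
            make_report("B", age=30, receipt_date=date(2010, 3, 1)),  # dup of A
            make_report("C", age=40, pts=("rash",), receipt_date=date(2011, 1, 1)),
            make_report("D", age=40, pts=("rash",), receipt_date=date(2010, 12, 1)),  # D earlier
            make_report("E", age=55, pts=("headache",)),
        ]
        db2, removed = deduplicate(make_db(reports))
        # oracle: brute-force comparison over all pairs on the key fields
        dup_pairs = {
            frozenset((r1.report_id, r2.report_id))
            for r1, r2 in itertools.combinations(reports, 2)
            if _dedup_key(r1, DEFAULT_DEDUP_KEY) == _dedup_key(r2, DEFAULT_DEDUP_KEY)
        }
        assert dup_pairs == {frozenset("AB"), frozenset("CD")}
        assert len(db2) == 3
        assert set(removed) == {"B", "C"}  # earliest date wins in each pair

    def test_idempotent(self):
        res = generate(SyntheticConfig(n_reports=300, seed=2, dup_rate=0.1))
        once, removed1 = deduplicate(res.db)
        twice, removed2 = deduplicate(once)
        assert removed2 == []
        assert once.report_ids == twice.report_ids


class TestExclusions:
    def test_literature_reports_dropped(self):
        r = make_report("L", source="literature")
        db2, dropped = apply_exclusions(make_db([r]), default_case_definition())
        assert dropped == {"L": "literature"}
        assert len(db2) == 0

    def test_vaccine_by_suspected_atc_prefix_only(self):
        vac = make_report("V", drugs=(("some vaccine", "J07BB02", "suspected"),))
        conc = make_report(
            "W",
            drugs=(
                ("aspirin", "N02BA01", "suspected"),
                ("some vaccine", "J07BB02", "concomitant"),
            ),
        )
        db2, dropped = apply_exclusions(make_db([vac, conc]), default_case_definition())
        assert dropped == {"V": "vaccine"}
        assert db2.report_ids == ["W"]

    def test_bare_vertigo_dropped_but_specified_diagnosis_kept(self):
        bare = make_report("B", pts=("vertigo",))
        ambiguous = make_report("A", pts=("vertigo", "nausea"))
        positional = make_report("P", pts=("vertigo positional",))
        both = make_report("C", pts=("vertigo", "tinnitus"))
        cd = default_case_definition()
        db2, dropped = apply_exclusions(make_db([bare, ambiguous, positional, both]), cd)
        assert dropped == {"B": "bare_vertigo", "A": "bare_vertigo"}
        cls = classify(db2, cd, dropped)
        assert set(cls.cases) == {"P", "C"}

    def test_keep_as_noncase_policy(self):
        bare = make_report("B", pts=("vertigo",))
        cd = default_case_definition(vertigo_policy="keep_as_noncase")
        db2, dropped = apply_exclusions(make_db([bare]), cd)
        assert dropped == {}
        assert classify(db2, cd).non_cases == ["B"]

    def test_precedence_window_then_literature_then_vaccine(self):
        cd = default_case_definition(
            window_start=date(2005, 1, 1), window_end=date(2015, 1, 1)
        )
        out = make_report("O", source="literature", receipt_date=date(2000, 1, 1))
        lit_vac = make_report(
            "LV", source="literature",
            drugs=(("some vaccine", "J07BB02", "suspected"),),
        )
        _, dropped = apply_exclusions(make_db([out, lit_vac]), cd)
        assert dropped == {"O": "out_of_window", "LV": "literature"}


class TestClassify:
    def test_report_with_several_case_pts_counts_once(self):
        r = make_report("M", pts=("tinnitus", "hypoacusis", "nausea"))
        cls = classify(make_db([r]), default_case_definition())
        assert cls.cases == ["M"]
        assert cls.n_cases == 1

    def test_non_case(self):
        r = make_report("N", pts=("nausea",))
        cls = classify(make_db([r]), default_case_definition())
        assert cls.non_cases == ["N"]

    def test_partition_property_on_synthetic_database(self):
        res = generate(
            SyntheticConfig(n_reports=2000, seed=4, dup_rate=0.02,
                            literature_rate=0.02, vaccine_rate=0.03,
                            bare_vertigo_rate=0.01)
        )
        cls, _ = partition(res.db, default_case_definition())
        assert cls.n_cases + cls.n_non_cases + len(cls.dropped) == len(res.db)
        assert not (set(cls.cases) & set(cls.non_cases))
        assert not (set(cls.cases) | set(cls.non_cases)) & set(cls.dropped)

    def test_classify_is_idempotent(self):
        res = generate(SyntheticConfig(n_reports=500, seed=9))
        cd = default_case_definition()
        db, dropped = apply_exclusions(res.db, cd)
        cls1 = classify(db, cd, dropped)
        cls2 = classify(db, cd, dropped)
        assert cls1.cases == cls2.cases
        assert cls1.non_cases == cls2.non_cases

    def test_enlarging_case_pts_is_monotone(self):
        res = generate(SyntheticConfig(n_reports=800, seed=3))
        small = default_case_definition()
        big = default_case_definition(
            case_pts=set(small.case_pts) | {"nausea", "synthetic pt 0001"}
        )
        db, _ = apply_exclusions(res.db, small)
        cases_small = set(classify(db, small).cases)
        cases_big = set(classify(db, big).cases)
        assert cases_small <= cases_big


class TestEventGroups:
    def test_deafness_group_membership(self):
        r = make_report("D", pts=("deafness unilateral",))
        assert event_group_membership(r, DEFAULT_EVENT_GROUPS) == {"deafness"}

    def test_multiple_groups(self):
        r = make_report("T", pts=("tinnitus", "neurosensory hypoacusis"))
        assert event_group_membership(r, DEFAULT_EVENT_GROUPS) == {
            "tinnitus", "hypoacusis",
        }

    def test_no_group(self):
        r = make_report("N", pts=("nausea",))
        assert event_group_membership(r, DEFAULT_EVENT_GROUPS) == set()

    def test_group_outside_case_list_is_configuration_error(self):
        r = make_report("X", pts=("tinnitus",))
        with pytest.raises(ConfigurationError, match="nausea"):
            event_group_membership(
                r, {"bad": {"nausea"}}, case_pts={"tinnitus"}
            )
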