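"""Shared fixtures and helpers for the otosignal test suite."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from otosignal import (
    DrugEntry,
    ReactionEntry,
    Report,
    ReportDatabase,
    default_case_definition,
    make_reference_fixture,
    partition,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_report(
    rid: str,
    pts=("nausea",),
    drugs=(("filler drug 001", None, "suspected"),),
    **kwargs,
) -> Report:
    defaults = dict(
        receipt_date=date(2010, 6, 15),
        age=50.0,
        sex="female",
        seriousness="not_serious",
        outcome="complete_recovery",
        source="spontaneous",
    )
    defaults.update(kwargs)
    return Report(
        report_id=rid,
        reactions=frozenset(ReactionEntry(p) for p in pts),
        drugs=tuple(DrugEntry(*d) for d in drugs),
        **defaults,
    )


def make_db(reports) -> ReportDatabase:
    return ReportDatabase(list(reports), provenance="test")


@pytest.fixture(scope="session")
def reference_classified():
    """Reference fixture, classified once per session: (cls, db)."""
    db = make_reference_fixture()
    cd = default_case_definition()
    cls, retained = partition(db, cd)
    return cls, retained
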