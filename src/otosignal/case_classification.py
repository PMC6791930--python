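"""Case/non-case partition of a spontaneous-reporting database.

A report is a *case* when at least one of its reactions belongs to the
configured PT case list; every other retained report is a *non-case*.
Before classification, study-style exclusion rules remove literature
reports, vaccine reports (suspected drug with an excluded ATC prefix,
J07 by default), reports outside the observation window, and reports
whose only ototoxicity-adjacent content is the ambiguous bare "vertigo"
term.  Counting is at the report level: a report with several case PTs
contributes exactly one case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .srs_data import Report, ReportDatabase, canonical, default_case_pt_list

#: PT-group mapping used for PT-specific screening.  "hypoacusis" includes
#: its neurosensory variant; "deafness" pools the deafness PTs and sudden
#: hearing loss.
DEFAULT_EVENT_GROUPS: dict[str, frozenset[str]] = {
    "tinnitus": frozenset({"tinnitus"}),
    "hypoacusis": frozenset({"hypoacusis", "neurosensory hypoacusis"}),
    "deafness": frozenset(
        {
            "deafness",
            "deafness bilateral",
            "deafness neurosensory",
            "deafness unilateral",
            "sudden hearing loss",
        }
    ),
}

DROP_REASONS = ("out_of_window", "literature", "duplicate", "vaccine", "bare_vertigo")


@dataclass
class CaseDefinition:
    """The included/excluded PT sets and exclusion-rule switches."""

    case_pts: frozenset[str]
    drop_pts: frozenset[str] = frozenset({"vertigo"})
    exclude_sources: frozenset[str] = frozenset({"literature"})
    exclude_atc_prefixes: frozenset[str] = frozenset({"J07"})
    window_start: date | None = None
    window_end: date | None = None
    #: "drop" removes bare-vertigo reports from the dataset entirely;
    #: "keep_as_noncase" retains them in the comparator group.
    vertigo_policy: str = "drop"

    def __post_init__(self) -> None:
        self.case_pts = frozenset(canonical(p) for p in self.case_pts)
        self.drop_pts = frozenset(canonical(p) for p in self.drop_pts)
        if not self.case_pts:
            raise ConfigurationError("case_pts must be non-empty")
        overlap = self.case_pts & self.drop_pts
        if overlap:
            raise ConfigurationError(
                f"case_pts and drop_pts overlap: {sorted(overlap)}"
            )
        if self.vertigo_policy not in ("drop", "keep_as_noncase"):
            raise ConfigurationError(
                f"invalid vertigo_policy: {self.vertigo_policy!r}"
            )
        self.exclude_atc_prefixes = frozenset(
            p.strip().upper() for p in self.exclude_atc_prefixes
        )


def default_case_definition(**overrides) -> CaseDefinition:
    """Ototoxicity case definition: the bundled 22-term PT list minus the
    bare "vertigo" term, which is excluded as clinically ambiguous."""
    drop_pts = frozenset(
        canonical(p) for p in overrides.pop("drop_pts", {"vertigo"})
    )
    case_pts = frozenset(overrides.pop("case_pts", default_case_pt_list()))
    return CaseDefinition(case_pts=case_pts - drop_pts, drop_pts=drop_pts, **overrides)


@dataclass
class ClassifiedDatabase:
    """Report ids partitioned into cases, non-cases and dropped."""

    cases: list[str]
    non_cases: list[str]
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = [set(self.cases), set(self.non_cases), set(self.dropped)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("cases, non_cases and dropped must be disjoint")
        self._case_set: frozenset[str] | None = None

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_non_cases(self) -> int:
        return len(self.non_cases)

    @property
    def case_set(self) -> frozenset[str]:
        if self._case_set is None:
            self._case_set = frozenset(self.cases)
        return self._case_set


_DEDUP_FIELDS = ("age", "sex", "receipt_date", "substances", "pts")
#: receipt_date is deliberately not part of the default key: duplicate
#: submissions of the same case typically differ in date.
DEFAULT_DEDUP_KEY = ("age", "sex", "substances", "pts")

_MAX_DATE = date.max


def _dedup_key(report: Report, key_fields: Sequence[str]) -> tuple:
    parts = []
    for f in key_fields:
        if f == "age":
            parts.append(report.age)
        elif f == "sex":
            parts.append(report.sex)
        elif f == "receipt_date":
            parts.append(report.receipt_date)
        elif f == "substances":
            parts.append(tuple(sorted(report.substances())))
        elif f == "pts":
            parts.append(tuple(sorted(report.pts)))
        else:
            raise ConfigurationError(f"invalid dedup key field: {f!r}")
    return tuple(parts)


def deduplicate(
    db: ReportDatabase, key_fields: Sequence[str] = DEFAULT_DEDUP_KEY
) -> tuple[ReportDatabase, list[str]]:
    """Remove exact-key duplicate reports.

    Among reports identical on all ``key_fields`` only the earliest
    ``receipt_date`` is retained (missing dates sort last; ties broken by
    the lexicographically smallest report_id).  Returns the deduplicated
    database and the removed ids for the audit log.
    """
    best: dict[tuple, Report] = {}
    for r in db.reports:
        k = _dedup_key(r, key_fields)
        cur = best.get(k)
        if cur is None:
            best[k] = r
            continue
        r_rank = (r.receipt_date or _MAX_DATE, r.report_id)
        cur_rank = (cur.receipt_date or _MAX_DATE, cur.report_id)
        if r_rank < cur_rank:
            best[k] = r
    keep_ids = {r.report_id for r in best.values()}
    kept = [r for r in db.reports if r.report_id in keep_ids]
    removed = [r.report_id for r in db.reports if r.report_id not in keep_ids]
    return ReportDatabase(kept, provenance=db.provenance), removed


def _drop_reason(report: Report, cd: CaseDefinition) -> str | None:
    """First matching exclusion rule, in the fixed precedence order
    window -> literature -> vaccine -> bare_vertigo."""
    if cd.window_start or cd.window_end:
        d = report.receipt_date
        if d is not None:
            if cd.window_start and d < cd.window_start:
                return "out_of_window"
            if cd.window_end and d > cd.window_end:
                return "out_of_window"
    if report.source in cd.exclude_sources:
        return "literature" if report.source == "literature" else report.source
    for drug in report.drugs:
        if (
            drug.role == "suspected"
            and drug.atc
            and drug.atc.startswith(tuple(cd.exclude_atc_prefixes))
        ):
            return "vaccine"
    if cd.vertigo_policy == "drop" and (report.pts & cd.drop_pts):
        if not (report.pts & cd.case_pts):
            return "bare_vertigo"
    return None


def apply_exclusions(
    db: ReportDatabase, cd: CaseDefinition
) -> tuple[ReportDatabase, dict[str, str]]:
    """Apply the exclusion rules, returning the retained database and a
    mapping report_id -> drop reason."""
    dropped: dict[str, str] = {}
    kept: list[Report] = []
    for r in db.reports:
        reason = _drop_reason(r, cd)
        if reason is None:
            kept.append(r)
        else:
            dropped[r.report_id] = reason
    return ReportDatabase(kept, provenance=db.provenance), dropped


def classify(
    db: ReportDatabase,
    cd: CaseDefinition,
    dropped: Mapping[str, str] | None = None,
) -> ClassifiedDatabase:
    """Partition an exclusion-filtered database into cases and non-cases.

    A report is a case iff its reactions intersect ``cd.case_pts``; a
    report with several case PTs still counts once.  ``dropped`` (from
    :func:`apply_exclusions` / :func:`deduplicate`) is carried through so
    the partition property cases + non_cases + dropped = input holds.
    """
    cases: list[str] = []
    non_cases: list[str] = []
    case_pts = cd.case_pts
    for r in db.reports:
        if r.pts & case_pts:
            cases.append(r.report_id)
        else:
            non_cases.append(r.report_id)
    return ClassifiedDatabase(cases, non_cases, dict(dropped or {}))


def partition(
    db: ReportDatabase,
    cd: CaseDefinition,
    dedup_key: Sequence[str] | None = DEFAULT_DEDUP_KEY,
) -> tuple[ClassifiedDatabase, ReportDatabase]:
    """Full chain: deduplicate, apply exclusions, classify.

    Returns the classification (with every dropped id and its reason) and
    the retained database the downstream stages should work from.
    """
    dropped: dict[str, str] = {}
    if dedup_key is not None:
        db, removed = deduplicate(db, dedup_key)
        dropped.update({rid: "duplicate" for rid in removed})
    db, excluded = apply_exclusions(db, cd)
    dropped.update(excluded)
    cls = classify(db, cd, dropped)
    return cls, db


def event_group_membership(
    report: Report,
    groups: Mapping[str, Iterable[str]],
    case_pts: Iterable[str] | None = None,
) -> set[str]:
    """All event groups with at least one matching PT on the report."""
    canon_groups = {
        name: frozenset(canonical(p) for p in pts) for name, pts in groups.items()
    }
    if case_pts is not None:
        allowed = frozenset(canonical(p) for p in case_pts)
        for name, pts in canon_groups.items():
            extra = pts - allowed
            if extra:
                raise ConfigurationError(
                    f"group {name!r} references PTs outside the case list: "
                    f"{sorted(extra)}"
                )
    return {name for name, pts in canon_groups.items() if report.pts & pts}
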