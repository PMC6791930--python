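"""Crude reporting odds ratios and SDR flagging.

For each drug-event pair a 2x2 table is built at the report level:

              exposed   unexposed
    cases        a          c
    non-cases    b          d

The reporting odds ratio is ``ROR = ad / (bc)`` with a Wald confidence
interval on the log scale, ``exp(ln ROR +/- z * sqrt(1/a+1/b+1/c+1/d))``
— algebraically the univariate logistic regression of case status on
exposure.  A signal of disproportionate reporting (SDR) is a pair whose
lower 95% confidence bound exceeds 1 with at least ``min_reports``
exposed case reports (3 by default).

Zero cells are handled with the Haldane–Anscombe correction (+0.5 to all
four cells), flagged via ``corrected=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .case_classification import (
    DEFAULT_EVENT_GROUPS,
    ClassifiedDatabase,
)
from .errors import DegenerateTableError
from .srs_data import Report, ReportDatabase, canonical

#: Pseudo event group meaning "any case PT at all".
ANY_OTOTOXICITY = "any_ototoxicity"


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case x exposed/unexposed counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int
    drug_key: str
    event_group: str = ANY_OTOTOXICITY

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            iv = int(v)
            if iv != v or iv < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
            object.__setattr__(self, name, iv)

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_non_cases(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    corrected: bool = False


@dataclass(frozen=True)
class SdrDecision:
    is_sdr: bool
    n_reports: int
    rule: str


@dataclass
class SignalResult:
    """One row of the screening output: a drug-event pair with counts,
    crude (and later adjusted) estimates, SDR flags and expectedness."""

    drug_key: str
    event_group: str
    table: ContingencyTable
    crude: RorEstimate
    sdr: SdrDecision
    adjusted: object | None = None  # AdjustedEstimate when the fit succeeds
    sdr_adjusted: SdrDecision | None = None
    fit_status: str = "not_attempted"
    expectedness: str = "unknown"


def _report_exposed(
    report: Report,
    drug_key: str,
    key_type: str = "substance",
    include_concomitant: bool = False,
) -> bool:
    for drug in report.drugs:
        if not include_concomitant and drug.role != "suspected":
            continue
        if key_type == "substance":
            if drug.substance == drug_key:
                return True
        elif key_type == "atc":
            if drug.atc and drug.atc.startswith(drug_key):
                return True
        else:
            raise ValueError(f"invalid key_type: {key_type!r}")
    return False


def _group_case_ids(
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    event_group: str,
    groups: Mapping[str, Iterable[str]],
) -> list[str]:
    if event_group == ANY_OTOTOXICITY:
        return list(cls.cases)
    try:
        pts = frozenset(canonical(p) for p in groups[event_group])
    except KeyError:
        raise KeyError(f"unknown event group: {event_group!r}") from None
    return [rid for rid in cls.cases if db.by_id(rid).pts & pts]


def build_table(
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    drug_key: str,
    event_group: str = ANY_OTOTOXICITY,
    groups: Mapping[str, Iterable[str]] | None = None,
    key_type: str = "substance",
    include_concomitant: bool = False,
) -> ContingencyTable:
    """Build the 2x2 table for one drug (or ATC-prefix) / event-group pair.

    Exposure means the key appears among a report's suspected drugs
    (optionally also concomitant); a report exposed through two entries
    counts once.  For a PT-specific group, case reports outside the group
    are excluded so that ``a + c`` equals the group's case total while
    ``b + d`` stays the full non-case count.
    """
    groups = groups or DEFAULT_EVENT_GROUPS
    key = drug_key.strip().upper() if key_type == "atc" else canonical(drug_key)
    case_ids = _group_case_ids(cls, db, event_group, groups)
    a = sum(
        1
        for rid in case_ids
        if _report_exposed(db.by_id(rid), key, key_type, include_concomitant)
    )
    b = sum(
        1
        for rid in cls.non_cases
        if _report_exposed(db.by_id(rid), key, key_type, include_concomitant)
    )
    return ContingencyTable(
        a=a,
        b=b,
        c=len(case_ids) - a,
        d=len(cls.non_cases) - b,
        drug_key=drug_key if key_type == "atc" else key,
        event_group=event_group,
    )


def crude_ror(
    t: ContingencyTable,
    alpha: float = 0.05,
    zero_cell_policy: str = "haldane",
) -> RorEstimate:
    """Crude ROR = ad/(bc) with the Wald CI on the log scale."""
    if zero_cell_policy not in ("haldane", "error"):
        raise ValueError(f"invalid zero_cell_policy: {zero_cell_policy!r}")
    cells = [t.a, t.b, t.c, t.d]
    corrected = False
    if any(v == 0 for v in cells):
        if zero_cell_policy == "error":
            name = "abcd"[cells.index(0)]
            raise DegenerateTableError(
                f"zero cell {name} in table for {t.drug_key}/{t.event_group}"
            )
        cells = [v + 0.5 for v in cells]
        corrected = True
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    z = norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RorEstimate(
        ror=ror,
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        alpha=alpha,
        corrected=corrected,
    )


def flag_sdr(
    e: RorEstimate, t: ContingencyTable, min_reports: int = 3
) -> SdrDecision:
    """SDR rule: lower CI bound above 1 with at least ``min_reports``
    exposed case reports."""
    return SdrDecision(
        is_sdr=(e.ci_low > 1.0) and (t.a >= min_reports),
        n_reports=t.a,
        rule=f"ci_low>1 and a>={min_reports}",
    )


def screen(
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    drug_universe: Sequence[str] | None = None,
    event_groups: Sequence[str] = (ANY_OTOTOXICITY,),
    groups: Mapping[str, Iterable[str]] | None = None,
    min_reports: int = 3,
    alpha: float = 0.05,
    include_concomitant: bool = False,
    zero_cell_policy: str = "haldane",
) -> list[SignalResult]:
    """Screen every drug in the universe against each event group.

    When ``drug_universe`` is None, the universe for each event group is
    every substance with at least ``min_reports`` exposed case reports.
    Output is deterministically ordered by event group, then descending
    ``a``, then drug key.
    """
    groups = groups or DEFAULT_EVENT_GROUPS
    case_set = cls.case_set
    non_case_ids = cls.non_cases

    def exposures(report: Report) -> frozenset[str]:
        if include_concomitant:
            return report.substances()
        return report.suspected_substances()

    # one counting pass per event group for a, one overall for b
    b_counts: dict[str, int] = {}
    for rid in non_case_ids:
        for s in exposures(db.by_id(rid)):
            b_counts[s] = b_counts.get(s, 0) + 1

    results: list[SignalResult] = []
    for group_name in event_groups:
        case_ids = _group_case_ids(cls, db, group_name, groups)
        a_counts: dict[str, int] = {}
        for rid in case_ids:
            for s in exposures(db.by_id(rid)):
                a_counts[s] = a_counts.get(s, 0) + 1
        if drug_universe is None:
            universe = sorted(
                s for s, n in a_counts.items() if n >= min_reports
            )
        else:
            universe = [canonical(s) for s in drug_universe]
        rows = []
        for substance in universe:
            a = a_counts.get(substance, 0)
            b = b_counts.get(substance, 0)
            t = ContingencyTable(
                a=a,
                b=b,
                c=len(case_ids) - a,
                d=len(non_case_ids) - b,
                drug_key=substance,
                event_group=group_name,
            )
            est = crude_ror(t, alpha=alpha, zero_cell_policy=zero_cell_policy)
            rows.append(
                SignalResult(
                    drug_key=substance,
                    event_group=group_name,
                    table=t,
                    crude=est,
                    sdr=flag_sdr(est, t, min_reports),
                )
            )
        rows.sort(key=lambda s: (-s.table.a, s.drug_key))
        results.extend(rows)
    return results
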