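"""Data model and I/O for individual case safety reports (ICSRs).

A spontaneous-reporting database is modelled as a list of :class:`Report`
objects, each holding patient demographics, one or more coded reactions
(MedDRA Preferred Terms) and one or more drugs (suspected or concomitant,
optionally ATC-coded).  On disk the canonical layout is a single flat
delimited table with one row per report x drug x reaction combination;
rows sharing a ``report_id`` are merged back into one report on read.

All term and substance matching is done on a canonical form: trimmed,
case-folded, internal whitespace collapsed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ConfigurationError, ConsistencyError, FormatError

logger = logging.getLogger(__name__)

SEX_VALUES = frozenset({"female", "male", "unknown"})
SERIOUSNESS_VALUES = frozenset({"serious", "not_serious", "not_available"})
SERIOUS_SUBTYPES = frozenset(
    {
        "death",
        "life_threatening",
        "hospitalization",
        "disability",
        "congenital_anomaly",
        "medically_important",
    }
)
OUTCOME_VALUES = frozenset(
    {
        "complete_recovery",
        "improvement",
        "not_yet_recovered",
        "recovered_with_sequelae",
        "death",
        "missing",
    }
)
SOURCE_VALUES = frozenset({"spontaneous", "literature", "other"})

#: ATC grammar: letter, 2 digits, letter, letter, 2 digits; truncations
#: (anatomical group, therapeutic/pharmacological subgroup, chemical
#: subgroup) are allowed for class-level codes.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

_WS_RE = re.compile(r"\s+")


def canonical(text: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return _WS_RE.sub(" ", str(text).strip()).casefold()


def is_valid_atc(code: str) -> bool:
    return bool(_ATC_RE.match(code))


@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One coded reaction: a MedDRA Preferred Term in canonical form."""

    pt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pt", canonical(self.pt))
        if not self.pt:
            raise ValueError("reaction PT is empty after trimming")


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug on a report: active substance, optional ATC code, role."""

    substance: str
    atc: str | None = None
    role: str = "suspected"

    def __post_init__(self) -> None:
        object.__setattr__(self, "substance", canonical(self.substance))
        if not self.substance:
            raise ValueError("drug substance is empty after trimming")
        if self.atc is not None:
            code = str(self.atc).strip().upper()
            if not is_valid_atc(code):
                raise ValueError(f"invalid ATC code: {self.atc!r}")
            object.__setattr__(self, "atc", code)
        if self.role not in ("suspected", "concomitant"):
            raise ValueError(f"invalid drug role: {self.role!r}")


@dataclass(slots=True)
class Report:
    """One spontaneous ADR report."""

    report_id: str
    reactions: frozenset[ReactionEntry]
    drugs: tuple[DrugEntry, ...]
    receipt_date: date | None = None
    age: float | None = None
    sex: str = "unknown"
    seriousness: str = "not_available"
    serious_subtype: str | None = None
    outcome: str = "missing"
    source: str = "spontaneous"
    pts: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: reactions empty")
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: drugs empty")
        if self.age is not None and self.age < 0:
            raise ValueError(f"report {self.report_id}: negative age")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"report {self.report_id}: invalid sex {self.sex!r}")
        if self.seriousness not in SERIOUSNESS_VALUES:
            raise ValueError(
                f"report {self.report_id}: invalid seriousness {self.seriousness!r}"
            )
        if self.serious_subtype is not None:
            if self.seriousness != "serious":
                raise ValueError(
                    f"report {self.report_id}: serious_subtype set on a "
                    f"non-serious report"
                )
            if self.serious_subtype not in SERIOUS_SUBTYPES:
                raise ValueError(
                    f"report {self.report_id}: invalid subtype "
                    f"{self.serious_subtype!r}"
                )
        if self.outcome not in OUTCOME_VALUES:
            raise ValueError(f"report {self.report_id}: invalid outcome")
        if self.source not in SOURCE_VALUES:
            raise ValueError(f"report {self.report_id}: invalid source")
        self.pts = frozenset(r.pt for r in self.reactions)

    def suspected_substances(self) -> frozenset[str]:
        return frozenset(d.substance for d in self.drugs if d.role == "suspected")

    def substances(self) -> frozenset[str]:
        return frozenset(d.substance for d in self.drugs)

    def n_drugs(self) -> int:
        """Number of drug entries, suspected and concomitant."""
        return len(self.drugs)


@dataclass
class ReportDatabase:
    """A collection of reports with unique ids."""

    reports: list[Report]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ConsistencyError(f"duplicate report_id: {i}")
                seen.add(i)
        self._index: dict[str, Report] | None = None

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    @property
    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def by_id(self, report_id: str) -> Report:
        if self._index is None:
            self._index = {r.report_id: r for r in self.reports}
        return self._index[report_id]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-report x drug x reaction table."""
        rows = []
        for r in self.reports:
            pts = sorted(r.pts)
            for d in r.drugs:
                for pt in pts:
                    rows.append(
                        (
                            r.report_id,
                            r.receipt_date.isoformat() if r.receipt_date else "",
                            "" if r.age is None else r.age,
                            r.sex,
                            r.seriousness,
                            r.serious_subtype or "",
                            r.outcome,
                            r.source,
                            d.substance,
                            d.atc or "",
                            d.role,
                            pt,
                        )
                    )
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


CANONICAL_COLUMNS = [
    "report_id",
    "receipt_date",
    "age",
    "sex",
    "seriousness",
    "serious_subtype",
    "outcome",
    "source",
    "substance",
    "atc",
    "role",
    "pt",
]

# Fields that must agree across all rows of one report_id.
_DEMOGRAPHIC_FIELDS = [
    "receipt_date",
    "age",
    "sex",
    "seriousness",
    "serious_subtype",
    "outcome",
    "source",
]


@dataclass(frozen=True)
class TableDialect:
    """Maps an on-disk table onto the canonical columns and coded values.

    ``columns`` maps canonical column name -> header in the file;
    ``value_maps`` maps a canonical column -> {raw value -> canonical value}.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    value_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    delimiter: str | None = None

    def header_for(self, canonical_name: str) -> str:
        return self.columns.get(canonical_name, canonical_name)


DEFAULT_DIALECT = TableDialect()


def _infer_delimiter(path: Path, dialect: TableDialect) -> str:
    if dialect.delimiter:
        return dialect.delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _map_enum(raw, value_map, allowed, missing_member, col, report_id=None):
    """Map a raw coded value to a canonical enum member.

    Unparseable values fall back to the missing/unknown member and are
    logged rather than raising: ingest keeps every report.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return missing_member
    text = canonical(raw)
    if value_map:
        mapped = {canonical(k): v for k, v in value_map.items()}.get(text)
        if mapped is not None:
            text = mapped
    if text in allowed:
        return text
    logger.warning(
        "unparseable %s value %r%s mapped to %r",
        col,
        raw,
        f" (report {report_id})" if report_id else "",
        missing_member,
    )
    return missing_member


def _parse_int_like(raw) -> float | None:
    """Parse a numeric field, accepting '.' and ',' thousands separators."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip()
    if re.fullmatch(r"\d{1,3}([.,]\d{3})+", text):
        text = re.sub(r"[.,]", "", text)
    return float(text)


def read_reports(path: str | Path, dialect: TableDialect | None = None) -> ReportDatabase:
    """Read a flat delimited ICSR table into a :class:`ReportDatabase`.

    Rows sharing a ``report_id`` are merged into one report taking the
    union of reactions and drugs; demographic fields must agree across
    those rows.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"reports file not found: {path}")
    dialect = dialect or DEFAULT_DIALECT
    df = pd.read_csv(
        path, sep=_infer_delimiter(path, dialect), dtype=str, keep_default_na=False
    )
    for col in CANONICAL_COLUMNS:
        header = dialect.header_for(col)
        if header not in df.columns:
            raise FormatError(f"missing mandatory column: {header!r} (for {col})")
    renames = {dialect.header_for(c): c for c in CANONICAL_COLUMNS}
    df = df.rename(columns=renames)

    reports: list[Report] = []
    for report_id, grp in df.groupby("report_id", sort=False):
        for fld in _DEMOGRAPHIC_FIELDS:
            vals = {v for v in grp[fld] if v != ""}
            if len(vals) > 1:
                raise ConsistencyError(
                    f"report {report_id}: conflicting {fld} values {sorted(vals)}"
                )
        first = grp.iloc[0]

        def _one(fld: str):
            vals = [v for v in grp[fld] if v != ""]
            return vals[0] if vals else ""

        rdate_raw = _one("receipt_date")
        rdate = date.fromisoformat(rdate_raw) if rdate_raw else None
        age = _parse_int_like(_one("age"))
        sex = _map_enum(_one("sex"), dialect.value_maps.get("sex"), SEX_VALUES,
                        "unknown", "sex", report_id)
        seriousness = _map_enum(
            _one("seriousness"), dialect.value_maps.get("seriousness"),
            SERIOUSNESS_VALUES, "not_available", "seriousness", report_id)
        subtype_raw = _one("serious_subtype")
        subtype = None
        if subtype_raw and seriousness == "serious":
            mapped = _map_enum(subtype_raw, dialect.value_maps.get("serious_subtype"),
                               SERIOUS_SUBTYPES, "", "serious_subtype", report_id)
            subtype = mapped or None
        outcome = _map_enum(_one("outcome"), dialect.value_maps.get("outcome"),
                            OUTCOME_VALUES, "missing", "outcome", report_id)
        source = _map_enum(_one("source"), dialect.value_maps.get("source"),
                           SOURCE_VALUES, "spontaneous", "source", report_id)

        reactions = frozenset(
            ReactionEntry(pt) for pt in grp["pt"] if str(pt).strip()
        )
        drugs: list[DrugEntry] = []
        seen_drugs: set[tuple] = set()
        for _, row in grp.iterrows():
            substance = str(row["substance"]).strip()
            if not substance:
                continue
            atc = str(row["atc"]).strip() or None
            role_raw = canonical(row["role"]) if row["role"] else "suspected"
            role_map = dialect.value_maps.get("role", {})
            role = {canonical(k): v for k, v in role_map.items()}.get(role_raw, role_raw)
            key = (canonical(substance), atc, role)
            if key not in seen_drugs:
                seen_drugs.add(key)
                drugs.append(DrugEntry(substance, atc, role))
        reports.append(
            Report(
                report_id=str(report_id),
                reactions=reactions,
                drugs=tuple(drugs),
                receipt_date=rdate,
                age=age,
                sex=sex,
                seriousness=seriousness,
                serious_subtype=subtype,
                outcome=outcome,
                source=source,
            )
        )
    return ReportDatabase(reports, provenance=f"read from {path}")


def write_reports(db: ReportDatabase, path: str | Path,
                  dialect: TableDialect | None = None) -> None:
    """Write a database back to the canonical flat table."""
    path = Path(path)
    dialect = dialect or DEFAULT_DIALECT
    df = db.to_frame()
    df.to_csv(path, sep=_infer_delimiter(path, dialect), index=False)


def read_pt_list(path: str | Path) -> set[str]:
    """Read a plain-text PT list (one term per line, ``#`` comments)."""
    path = Path(path)
    terms: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        terms.add(canonical(line))
    if not terms:
        raise ConfigurationError(f"PT list {path} contains no terms")
    return terms


_EXPECTED_DIALECT = {"yes": "expected", "no": "unexpected"}


def read_reference_labels(path: str | Path) -> dict[tuple[str, str], str]:
    """Read the expectedness reference table.

    Columns: ``substance``, ``event_group``, ``expected`` (yes/no, where
    "yes" means the reaction is acknowledged in the product label).
    Pairs absent from the table are reported as ``"unknown"`` at lookup.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("substance", "event_group", "expected"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    labels: dict[tuple[str, str], str] = {}
    for _, row in df.iterrows():
        raw = canonical(row["expected"])
        if raw not in _EXPECTED_DIALECT:
            raise FormatError(
                f"expected column value {row['expected']!r} outside yes/no"
            )
        labels[(canonical(row["substance"]), canonical(row["event_group"]))] = (
            _EXPECTED_DIALECT[raw]
        )
    return labels


def lookup_expectedness(labels: Mapping[tuple[str, str], str],
                        substance: str, event_group: str) -> str:
    return labels.get((canonical(substance), canonical(event_group)), "unknown")


def read_atc_mapping(path: str | Path) -> dict[str, str]:
    """Read a substance -> ATC code mapping (columns substance, atc)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("substance", "atc"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        code = str(row["atc"]).strip().upper()
        if code and not is_valid_atc(code):
            raise FormatError(f"invalid ATC code {row['atc']!r}")
        mapping[canonical(row["substance"])] = code
    return mapping


def default_case_pt_list() -> set[str]:
    """The bundled ototoxicity PT case list (22 MedDRA Preferred Terms)."""
    from importlib.resources import files

    with files("otosignal.data").joinpath("ototoxicity_pts.txt").open(
        "r", encoding="utf-8"
    ) as fh:
        terms = {
            canonical(line)
            for line in fh
            if line.strip() and not line.startswith("#")
        }
    return terms


def default_reference_labels() -> dict[tuple[str, str], str]:
    """The bundled expectedness reference table."""
    from importlib.resources import files

    return read_reference_labels(
        files("otosignal.data").joinpath("reference_labels.csv")
    )
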