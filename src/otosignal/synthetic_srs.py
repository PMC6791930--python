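"""Synthetic spontaneous-reporting databases with known ground truth.

Two generators live here:

* :func:`generate` draws a seeded database from a configurable
  probabilistic model — covariates (age, sex, polypharmacy), per-drug
  exposure logits, and a logistic event model with designed drug-event
  log-odds ``theta`` and confounding through age, sex and number of
  drugs.  The returned ground truth makes every pipeline stage testable
  against the design values.

* :func:`make_reference_fixture` deterministically builds a database
  whose classification reproduces a published ototoxicity cohort's
  marginal counts exactly (652 cases vs 325,328 non-cases, the case
  demographic/seriousness/outcome breakdowns, and configurable per-drug
  exposure counts such as amikacin 16/119 and cisplatin 34/1,731).
  Filler content is synthetic and carries no real MedDRA/ATC meaning.

Within the generator, age and drug-count covariates are standardized
(z-scores of the realized draws) so the logit coefficients are
scale-free; the sex coefficient multiplies a male indicator (female
reference), matching the coding used by the adjusted-regression module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .srs_data import DrugEntry, ReactionEntry, Report, ReportDatabase

_BASE_DATE = date(2001, 12, 1)
_N_DAYS = 5874  # through 2017-12-31

#: representative PT per event group used when an event fires
_GROUP_PTS = {
    "tinnitus": "tinnitus",
    "hypoacusis": "hypoacusis",
    "deafness": "deafness",
    "other": "vertigo positional",
}

_ATC_LETTERS = "ABCDGHLMNPRSV"


def _filler_atc(i: int) -> str:
    """Deterministic synthetic ATC-like code for filler drug i (never J07)."""
    l1 = _ATC_LETTERS[i % len(_ATC_LETTERS)]
    return f"{l1}{(i // 7) % 90 + 10:02d}A" + "ABCDEF"[i % 6] + f"{i % 90 + 10:02d}"


@dataclass(frozen=True)
class FocalDrug:
    """One designed drug: exposure model plus its event log-odds."""

    name: str
    theta: float = 0.0  # log-OR on the event logit
    gamma0: float = -4.6  # baseline exposure logit (~1%)
    gamma_age: float = 0.0
    gamma_sex: float = 0.0  # multiplies the male indicator
    gamma_ndrugs: float = 0.0
    atc: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic reporting database.

    Defaults emulate a national-scale spontaneous reporting system: a
    10^5-scale report set, ~0.2% ototoxicity prevalence, an elderly-
    skewed age mixture, mild female predominance and 1 + Poisson(1.5)
    drugs per report, with one designed association (OR 4) confounded
    by age.
    """

    n_reports: int = 100_000
    seed: int = 0
    age_weights: tuple[float, ...] = (0.35, 0.65)
    age_means: tuple[float, ...] = (38.0, 70.0)
    age_sds: tuple[float, ...] = (13.0, 9.0)
    p_female: float = 0.56
    n_drugs_lambda: float = 1.5
    focal_drugs: tuple[FocalDrug, ...] = (
        FocalDrug("focal drug a", theta=math.log(4.0),
                  gamma0=-4.6, gamma_age=0.3),
    )
    beta0: float = -6.2146  # logit of ~0.2% baseline event probability
    beta_age: float = 0.3
    beta_sex: float = 0.0
    beta_ndrugs: float = 0.0
    group_weights: tuple[tuple[str, float], ...] = (
        ("tinnitus", 0.55),
        ("hypoacusis", 0.33),
        ("deafness", 0.03),
        ("other", 0.09),
    )
    n_filler_drugs: int = 200
    n_filler_pts: int = 500
    missing_age_rate: float = 0.03
    missing_sex_rate: float = 0.007
    dup_rate: float = 0.01
    literature_rate: float = 0.01
    vaccine_rate: float = 0.02
    bare_vertigo_rate: float = 0.002
    #: when True a case report may carry a second case PT from another group
    multi_pt: bool = False
    multi_pt_rate: float = 0.1

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_reports <= 0:
            bad.append("n_reports")
        if not (
            len(self.age_weights) == len(self.age_means) == len(self.age_sds)
            and abs(sum(self.age_weights) - 1) < 1e-9
            and all(w >= 0 for w in self.age_weights)
            and all(s > 0 for s in self.age_sds)
        ):
            bad.append("age_mixture")
        if not 0 <= self.p_female <= 1:
            bad.append("p_female")
        if self.n_drugs_lambda <= 0:
            bad.append("n_drugs_lambda")
        names = [f.name for f in self.focal_drugs]
        if len(set(names)) != len(names):
            bad.append("focal_drugs")
        gw = dict(self.group_weights)
        if abs(sum(gw.values()) - 1) > 1e-9 or any(w < 0 for w in gw.values()) \
                or not set(gw) <= set(_GROUP_PTS):
            bad.append("group_weights")
        for rate_name in ("missing_age_rate", "missing_sex_rate", "dup_rate",
                          "literature_rate", "vaccine_rate", "bare_vertigo_rate",
                          "multi_pt_rate"):
            v = getattr(self, rate_name)
            if not 0 <= v <= 1:
                bad.append(rate_name)
        if self.n_filler_drugs < 1 or self.n_filler_pts < 1:
            bad.append("filler_pools")
        if bad:
            raise ValidationError(f"invalid SyntheticConfig fields: {bad}")


class SyntheticResult(NamedTuple):
    db: ReportDatabase
    truth: pd.DataFrame


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate(cfg: SyntheticConfig) -> SyntheticResult:
    """Draw a seeded synthetic database plus its ground-truth table.

    The same config (including seed) regenerates the identical database
    byte for byte.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    comp = rng.choice(len(cfg.age_weights), size=n, p=np.asarray(cfg.age_weights))
    age = rng.normal(np.asarray(cfg.age_means)[comp], np.asarray(cfg.age_sds)[comp])
    age = np.clip(age, 0.0, 100.0)
    male = (rng.random(n) >= cfg.p_female).astype(int)
    n_drugs_draw = 1 + rng.poisson(cfg.n_drugs_lambda, size=n)

    age_z = _zscore(age)
    nd_z = _zscore(n_drugs_draw.astype(float))

    exposed = np.zeros((n, len(cfg.focal_drugs)), dtype=bool)
    for j, fd in enumerate(cfg.focal_drugs):
        logit = (
            fd.gamma0 + fd.gamma_age * age_z + fd.gamma_sex * male
            + fd.gamma_ndrugs * nd_z
        )
        exposed[:, j] = rng.random(n) < _expit(logit)

    event_logit = (
        cfg.beta0 + cfg.beta_age * age_z + cfg.beta_sex * male
        + cfg.beta_ndrugs * nd_z
    )
    for j, fd in enumerate(cfg.focal_drugs):
        event_logit = event_logit + fd.theta * exposed[:, j]
    event = rng.random(n) < _expit(event_logit)

    group_names = [g for g, _ in cfg.group_weights]
    group_p = np.asarray([w for _, w in cfg.group_weights])
    group_idx = rng.choice(len(group_names), size=n, p=group_p)
    second_group = rng.random(n) < (cfg.multi_pt_rate if cfg.multi_pt else 0.0)

    filler_pt_idx = rng.integers(0, cfg.n_filler_pts, size=n)
    filler_drug_base = rng.integers(0, cfg.n_filler_drugs, size=n)
    dates = np.asarray(
        [_BASE_DATE + timedelta(days=int(d)) for d in rng.integers(0, _N_DAYS, n)]
    )
    literature = rng.random(n) < cfg.literature_rate
    vaccine = rng.random(n) < cfg.vaccine_rate
    bare_vertigo = (~event) & (rng.random(n) < cfg.bare_vertigo_rate)
    miss_age = rng.random(n) < cfg.missing_age_rate
    miss_sex = rng.random(n) < cfg.missing_sex_rate
    serious = rng.random(n) < 0.33
    outcome_pool = np.asarray(
        ["complete_recovery", "improvement", "not_yet_recovered",
         "recovered_with_sequelae", "missing"]
    )
    outcome_idx = rng.choice(5, size=n, p=[0.40, 0.27, 0.08, 0.02, 0.23])

    # interned entry objects: filler vocabulary is small, reuse saves memory
    _drug_cache: dict[tuple, DrugEntry] = {}

    def drug_entry(substance: str, atc: str | None, role: str) -> DrugEntry:
        key = (substance, atc, role)
        e = _drug_cache.get(key)
        if e is None:
            e = DrugEntry(substance, atc, role)
            _drug_cache[key] = e
        return e

    _pt_cache: dict[str, ReactionEntry] = {}

    def reaction(pt: str) -> ReactionEntry:
        e = _pt_cache.get(pt)
        if e is None:
            e = ReactionEntry(pt)
            _pt_cache[pt] = e
        return e

    vaccine_entry = drug_entry("synthetic vaccine", "J07AX01", "suspected")
    focal_entries = [
        drug_entry(fd.name, fd.atc, "suspected") for fd in cfg.focal_drugs
    ]

    reports: list[Report] = []
    width = len(str(n))
    for i in range(n):
        drugs: list[DrugEntry] = [
            focal_entries[j] for j in range(len(cfg.focal_drugs)) if exposed[i, j]
        ]
        if vaccine[i]:
            drugs.append(vaccine_entry)
        total = max(int(n_drugs_draw[i]), len(drugs))
        base = int(filler_drug_base[i])
        k = 0
        while len(drugs) < total:
            idx = (base + k) % cfg.n_filler_drugs
            role = "suspected" if not drugs else "concomitant"
            drugs.append(
                drug_entry(f"filler drug {idx:03d}", _filler_atc(idx), role)
            )
            k += 1

        if bare_vertigo[i]:
            reactions = frozenset({reaction("vertigo")})
        elif event[i]:
            pts = {_GROUP_PTS[group_names[group_idx[i]]]}
            if second_group[i]:
                alt = group_names[(group_idx[i] + 1) % len(group_names)]
                pts.add(_GROUP_PTS[alt])
            reactions = frozenset(reaction(p) for p in pts)
        else:
            reactions = frozenset(
                {reaction(f"synthetic pt {int(filler_pt_idx[i]):04d}")}
            )

        reports.append(
            Report(
                report_id=f"S{i:0{width}d}",
                reactions=reactions,
                drugs=tuple(drugs),
                receipt_date=dates[i],
                age=None if miss_age[i] else float(round(age[i], 1)),
                sex="unknown" if miss_sex[i] else ("male" if male[i] else "female"),
                seriousness="serious" if serious[i] else "not_serious",
                serious_subtype="medically_important" if serious[i] else None,
                outcome=str(outcome_pool[outcome_idx[i]]),
                source="literature" if literature[i] else "spontaneous",
            )
        )

    # injected duplicates: copies with a new id and a later receipt date
    n_dup = int(round(cfg.dup_rate * n))
    dup_src = rng.choice(n, size=n_dup, replace=False) if n_dup else []
    for i in sorted(int(x) for x in dup_src):
        orig = reports[i]
        reports.append(
            Report(
                report_id=orig.report_id + "-dup",
                reactions=orig.reactions,
                drugs=orig.drugs,
                receipt_date=orig.receipt_date + timedelta(days=30),
                age=orig.age,
                sex=orig.sex,
                seriousness=orig.seriousness,
                serious_subtype=orig.serious_subtype,
                outcome=orig.outcome,
                source=orig.source,
            )
        )

    truth = pd.DataFrame(
        {
            "report_id": [f"S{i:0{width}d}" for i in range(n)],
            "event": event,
            "group": [
                group_names[group_idx[i]] if event[i] else "" for i in range(n)
            ],
            "age": age,
            "male": male,
            "n_drugs": n_drugs_draw,
            "literature": literature,
            "vaccine": vaccine,
            "bare_vertigo": bare_vertigo,
        }
    )
    for j, fd in enumerate(cfg.focal_drugs):
        truth[f"exposed_{fd.name}"] = exposed[:, j]

    db = ReportDatabase(
        reports, provenance=f"synthetic (seed={cfg.seed}, n={n})"
    )
    return SyntheticResult(db, truth)


# --------------------------------------------------------------------------
# Deterministic reference fixture
# --------------------------------------------------------------------------

#: default per-drug exposure design: substance -> (ATC, cases by PT segment,
#: number of exposed non-cases)
_DEFAULT_DRUG_COUNTS: dict[str, dict] = {
    "amikacin": {
        "atc": "J01GB06",
        "cases_by_group": {"hypoacusis": 10, "tinnitus": 5, "other": 1},
        "non_cases": 119,
    },
    "cisplatin": {
        "atc": "L01XA01",
        "cases_by_group": {"hypoacusis": 19, "tinnitus": 13, "other": 2},
        "non_cases": 1731,
    },
}

_N_CASES = 652
_N_NON_CASES = 325_328

# case PT segments: [start, stop) index ranges within the 652 cases
_CASE_PT_SEGMENTS: list[tuple[str, int]] = [
    ("tinnitus", 358),
    ("hypoacusis", 183),
    ("neurosensory hypoacusis", 30),
    ("deafness", 9),
    ("deafness bilateral", 4),
    ("deafness neurosensory", 3),
    ("deafness unilateral", 2),
    ("sudden hearing loss", 3),
    ("vertigo positional", 40),
    ("vestibular disorder", 10),
    ("ear disorder", 5),
    ("hyperacusis", 5),
]
# index ranges (within cases) of the three screened groups + "other"
_GROUP_RANGES = {
    "tinnitus": (0, 358),
    "hypoacusis": (358, 571),
    "deafness": (571, 592),
    "other": (592, 652),
}

_CASE_SEX = [("female", 337), ("male", 312), ("unknown", 3)]
_NC_SEX = [("female", 182_226), ("male", 140_753), ("unknown", 2_349)]
_CASE_SERIOUS = [
    (("serious", "medically_important"), 82),
    (("serious", "hospitalization"), 59),
    (("serious", "disability"), 42),
    (("serious", "life_threatening"), 4),
    (("not_serious", None), 408),
    (("not_available", None), 57),
]
_NC_SERIOUS = [
    (("serious", "medically_important"), 113_127),
    (("not_serious", None), 195_525),
    (("not_available", None), 16_676),
]
_CASE_OUTCOME = [
    ("complete_recovery", 203),
    ("improvement", 131),
    ("not_yet_recovered", 128),
    ("recovered_with_sequelae", 23),
    ("missing", 167),
]
_NC_OUTCOME = [
    ("complete_recovery", 136_366),
    ("improvement", 92_945),
    ("not_yet_recovered", 20_121),
    ("recovered_with_sequelae", 5_400),
    ("death", 3_756),
    ("missing", 66_740),
]
# ages: sorted known-age vectors anchored so that the linear-interpolation
# quartiles reproduce median (Q1-Q3) = 60 (45-70) for cases and 61 (44-74)
# for non-cases, with the printed <18 / 18-64 / >=65 / missing band counts
_CASE_AGE = {
    "n_missing": 31,
    "knots": [(0, 1), (16, 17), (17, 18), (155, 45), (310, 60), (375, 64),
              (376, 65), (465, 70), (620, 95)],
    "n_known": 621,
}
_NC_AGE = {
    "n_missing": 10_247,
    "knots": [(0, 0), (19_317, 17), (19_318, 18), (78_770, 44), (157_540, 61),
              (175_624, 64), (175_625, 65), (236_310, 74), (315_080, 100)],
    "n_known": 315_081,
}
# drug-count vectors anchored to median (Q1-Q3) = 2 (1-3) / 2 (1-4)
_CASE_NDRUGS = [(1, 200), (2, 180), (3, 180), (4, 92)]
_NC_NDRUGS = [(1, 90_000), (2, 80_000), (3, 60_000), (4, 95_328)]


def _expand_blocks(blocks: Sequence[tuple]) -> list:
    out: list = []
    for value, count in blocks:
        out.extend([value] * count)
    return out


def _anchored_ages(spec: dict) -> list[float]:
    pos = np.arange(spec["n_known"])
    xp = [p for p, _ in spec["knots"]]
    fp = [v for _, v in spec["knots"]]
    return [float(v) for v in np.round(np.interp(pos, xp, fp))]


def make_reference_fixture(
    drug_counts: dict[str, dict] | None = None,
) -> ReportDatabase:
    """Deterministic benchmark database reproducing published marginals.

    Classification of the result yields exactly 652 cases and 325,328
    non-cases with the published case-column sex, age-band, seriousness
    (incl. subtype) and outcome counts, PT-group sizes (tinnitus 358,
    hypoacusis 213, deafness 21), and the requested per-drug exposure
    counts (default: amikacin 16 cases / 119 non-cases, cisplatin
    34 / 1,731).  Every report also carries one globally unique synthetic
    filler PT so that exact-key deduplication is a no-op on the fixture.
    """
    drug_counts = _DEFAULT_DRUG_COUNTS if drug_counts is None else drug_counts

    for name, d in drug_counts.items():
        for g in d["cases_by_group"]:
            if g not in _GROUP_RANGES:
                raise ValidationError(f"{name}: unknown group {g!r}")
    if sum(sum(d["cases_by_group"].values()) for d in drug_counts.values()) > _N_CASES:
        raise ValidationError("requested case exposures exceed the case total")
    if sum(d["non_cases"] for d in drug_counts.values()) > _N_NON_CASES:
        raise ValidationError("requested non-case exposures exceed the total")
    for g, (lo, hi) in _GROUP_RANGES.items():
        asked = sum(d["cases_by_group"].get(g, 0) for d in drug_counts.values())
        if asked > hi - lo:
            raise ValidationError(f"group {g!r}: requested exposures exceed size")

    # --- per-report attribute vectors (block-assigned; marginals exact) ---
    case_pts = _expand_blocks(_CASE_PT_SEGMENTS)
    case_sex = _expand_blocks(_CASE_SEX)
    nc_sex = _expand_blocks(_NC_SEX)
    case_serious = _expand_blocks(_CASE_SERIOUS)
    nc_serious = _expand_blocks(_NC_SERIOUS)
    case_outcome = _expand_blocks(_CASE_OUTCOME)
    nc_outcome = _expand_blocks(_NC_OUTCOME)
    case_ages = _anchored_ages(_CASE_AGE) + [None] * _CASE_AGE["n_missing"]
    nc_ages = _anchored_ages(_NC_AGE) + [None] * _NC_AGE["n_missing"]
    case_nd = _expand_blocks(_CASE_NDRUGS)
    nc_nd = _expand_blocks(_NC_NDRUGS)

    # --- exposure assignment ---
    case_drug: dict[int, tuple[str, str | None]] = {}
    next_free = {g: lo for g, (lo, hi) in _GROUP_RANGES.items()}
    for name, d in drug_counts.items():
        for g, k in d["cases_by_group"].items():
            start = next_free[g]
            for i in range(start, start + k):
                case_drug[i] = (name, d.get("atc"))
            next_free[g] = start + k
    # non-case exposures spread over the index range with a prime stride so
    # exposure does not line up with the block-assigned demographics
    nc_drug: dict[int, tuple[str, str | None]] = {}
    stride, j = 9973, 0
    for name, d in drug_counts.items():
        for _ in range(d["non_cases"]):
            nc_drug[(j * stride) % _N_NON_CASES] = (name, d.get("atc"))
            j += 1
    assert len(nc_drug) == j, "stride must enumerate distinct positions"

    n_fill = 200
    _drug_cache: dict[tuple, DrugEntry] = {}

    def drug_entry(substance, atc, role):
        key = (substance, atc, role)
        e = _drug_cache.get(key)
        if e is None:
            e = DrugEntry(substance, atc, role)
            _drug_cache[key] = e
        return e

    def build_drugs(global_i: int, n_drugs: int,
                    exposure: tuple[str, str | None] | None) -> tuple[DrugEntry, ...]:
        drugs: list[DrugEntry] = []
        if exposure is not None:
            drugs.append(drug_entry(exposure[0], exposure[1], "suspected"))
        k = 0
        while len(drugs) < n_drugs:
            idx = (global_i + 41 * k) % n_fill
            role = "suspected" if not drugs else "concomitant"
            drugs.append(
                drug_entry(f"filler drug {idx:03d}", _filler_atc(idx), role)
            )
            k += 1
        return tuple(drugs)

    case_pt_cache = {pt: ReactionEntry(pt) for pt, _ in _CASE_PT_SEGMENTS}

    reports: list[Report] = []
    for i in range(_N_CASES):
        d = _BASE_DATE + timedelta(days=i % _N_DAYS)
        seriousness, subtype = case_serious[i]
        reports.append(
            Report(
                report_id=f"C{i:06d}",
                reactions=frozenset(
                    {case_pt_cache[case_pts[i]],
                     ReactionEntry(f"synthetic background pt c{i:06d}")}
                ),
                drugs=build_drugs(i, case_nd[i], case_drug.get(i)),
                receipt_date=d,
                age=case_ages[i],
                sex=case_sex[i],
                seriousness=seriousness,
                serious_subtype=subtype,
                outcome=case_outcome[i],
                source="spontaneous",
            )
        )
    for i in range(_N_NON_CASES):
        seriousness, subtype = nc_serious[i]
        reports.append(
            Report(
                report_id=f"N{i:06d}",
                reactions=frozenset(
                    {ReactionEntry(f"synthetic background pt n{i:06d}")}
                ),
                drugs=build_drugs(_N_CASES + i, nc_nd[i], nc_drug.get(i)),
                receipt_date=_BASE_DATE + timedelta(days=i % _N_DAYS),
                age=nc_ages[i],
                sex=nc_sex[i],
                seriousness=seriousness,
                serious_subtype=subtype,
                outcome=nc_outcome[i],
                source="spontaneous",
            )
        )
    return ReportDatabase(reports, provenance="deterministic reference fixture")
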