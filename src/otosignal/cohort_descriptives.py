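"""Cohort descriptives: cases vs non-cases comparison tables.

Reproduces the standard pharmacovigilance cohort table: counts with
percentages, medians with interquartile ranges, Pearson chi-squared for
categorical variables, Mann-Whitney U for continuous ones, and a
Kolmogorov-Smirnov normality gate deciding the non-parametric path.

Percentage denominators include missing-value rows (the group total),
while hypothesis tests exclude missing categories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .case_classification import DEFAULT_EVENT_GROUPS, ClassifiedDatabase
from .errors import DegenerateInputError, DegenerateTableError
from .srs_data import ReportDatabase


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for display values (52.35 -> 52.4)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def chisq_2xk(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2 x k contingency table (no continuity
    correction), returning the statistic and its upper-tail p-value."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise DegenerateTableError("a cell has zero expected count")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all assignments of the
    pooled sample to the two groups.  Ties contribute 1/2 to U; the
    two-sided p is twice the smaller tail of the enumerated U
    distribution (capped at 1), so tied, unbalanced instances — where
    that distribution is asymmetric — are handled exactly."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)

    def u_of(idx: tuple[int, ...]) -> float:
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        xs, ys = pooled[sel], pooled[~sel]
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(tuple(range(nx)))
    eps = 1e-12
    le = ge = 0
    total = 0
    for idx in itertools.combinations(range(n), nx):
        u = u_of(idx)
        le += u <= u_obs + eps
        ge += u >= u_obs - eps
        total += 1
    p = 2.0 * min(le, ge) / total
    return float(u_obs), min(1.0, p)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str | None = None
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``mode`` is ``"exact_small"`` (full enumeration, default when
    n_x + n_y <= 12) or ``"normal_approx"`` (tie-corrected normal
    approximation with continuity correction).  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode is None:
        mode = "exact_small" if len(x) + len(y) <= 12 else "normal_approx"
    if mode == "exact_small":
        return _exact_mwu(x, y)
    if mode == "normal_approx":
        if np.all(x[0] == np.concatenate([x, y])):
            return float(len(x) * len(y) / 2.0), 1.0
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"invalid mode: {mode!r}")


def ks_normality(
    x: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with moments estimated from the sample.

    Estimating the moments from the same data makes the test
    conservative (approximate); it is used only as a gate for choosing
    the non-parametric comparison path.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise DegenerateInputError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance sample")
    d, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(d), float(p), bool(p > alpha)


@dataclass
class CohortSummary:
    """Per-variable descriptives for cases vs non-cases.

    ``variables`` maps a variable name to a dict with per-group entries
    (counts, percentages or median/IQR) plus the test name, statistic and
    p-value where a comparison applies.
    """

    n_cases: int
    n_non_cases: int
    variables: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, entry in self.variables.items():
            rows.append(
                {
                    "variable": var,
                    "cases": entry.get("cases"),
                    "cases_pct": entry.get("cases_pct"),
                    "non_cases": entry.get("non_cases"),
                    "non_cases_pct": entry.get("non_cases_pct"),
                    "test": entry.get("test"),
                    "statistic": entry.get("statistic"),
                    "p_value": entry.get("p_value"),
                }
            )
        return pd.DataFrame(rows)

    def format_text(self) -> str:
        df = self.to_frame()
        lines = [f"Cases n={self.n_cases}  Non-cases n={self.n_non_cases}", ""]
        for _, row in df.iterrows():
            cases = row["cases"]
            if row["cases_pct"] is not None and not pd.isna(row["cases_pct"]):
                cases = f"{cases} ({row['cases_pct']})"
            nc = row["non_cases"]
            if row["non_cases_pct"] is not None and not pd.isna(
                row["non_cases_pct"]
            ):
                nc = f"{nc} ({row['non_cases_pct']})"
            p = ""
            if row["p_value"] is not None and not pd.isna(row["p_value"]):
                p = f"p={row['p_value']:.3g}"
            lines.append(f"{row['variable']:<42}{cases!s:>20}{nc!s:>20}  {p}")
        return "\n".join(lines)


def _pct(n: int, denom: int) -> float | None:
    return None if denom == 0 else round_half_up(100.0 * n / denom, 1)


def _median_iqr(values: list[float]) -> tuple[float, float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return med, q1, q3


def _age_band(age: float) -> str:
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    return ">=65"


def summarize(
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> CohortSummary:
    """Build the cases vs non-cases descriptive comparison."""
    groups = groups or DEFAULT_EVENT_GROUPS
    case_reports = [db.by_id(i) for i in cls.cases]
    nc_reports = [db.by_id(i) for i in cls.non_cases]
    n_cases, n_nc = len(case_reports), len(nc_reports)
    summary = CohortSummary(n_cases=n_cases, n_non_cases=n_nc)
    V = summary.variables

    def count(reports, pred):
        return sum(1 for r in reports if pred(r))

    def add(var, c_n, nc_n, test=None, statistic=None, p=None):
        V[var] = {
            "cases": c_n,
            "cases_pct": _pct(c_n, n_cases),
            "non_cases": nc_n,
            "non_cases_pct": _pct(nc_n, n_nc),
            "test": test,
            "statistic": statistic,
            "p_value": p,
        }

    def safe_chisq(table):
        try:
            return chisq_2xk(table)
        except (DegenerateTableError, ValueError):
            return None, None

    # --- sex ---
    sex_counts = {
        g: {s: count(rep, lambda r, s=s: r.sex == s) for s in ("female", "male", "unknown")}
        for g, rep in (("cases", case_reports), ("non_cases", nc_reports))
    }
    stat, p = (None, None)
    if n_cases and n_nc:
        stat, p = safe_chisq(
            [
                [sex_counts["cases"]["female"], sex_counts["cases"]["male"]],
                [sex_counts["non_cases"]["female"], sex_counts["non_cases"]["male"]],
            ]
        )
    add("sex: female", sex_counts["cases"]["female"], sex_counts["non_cases"]["female"],
        "pearson_chi2", stat, p)
    add("sex: male", sex_counts["cases"]["male"], sex_counts["non_cases"]["male"])
    add("sex: missing", sex_counts["cases"]["unknown"], sex_counts["non_cases"]["unknown"])
    for g, rep in (("cases", case_reports), ("non_cases", nc_reports)):
        m = sex_counts[g]["male"]
        V[f"female/male ratio ({g})"] = {
            "cases": round_half_up(sex_counts[g]["female"] / m, 1) if m else None,
            "cases_pct": None, "non_cases": None, "non_cases_pct": None,
            "test": None, "statistic": None, "p_value": None,
        }

    # --- age ---
    ages_c = [r.age for r in case_reports if r.age is not None]
    ages_nc = [r.age for r in nc_reports if r.age is not None]
    stat, p = (None, None)
    if ages_c and ages_nc:
        stat, p = mann_whitney(ages_c, ages_nc)
    for name, vals in (("cases", ages_c), ("non_cases", ages_nc)):
        mi = _median_iqr(vals)
        V[f"median age ({name})"] = {
            "cases": None if mi is None else f"{mi[0]:g} ({mi[1]:g}-{mi[2]:g})",
            "cases_pct": None, "non_cases": None, "non_cases_pct": None,
            "test": "mann_whitney" if name == "cases" else None,
            "statistic": stat if name == "cases" else None,
            "p_value": p if name == "cases" else None,
        }
    band_counts = {
        g: {
            b: sum(1 for a in vals if _age_band(a) == b)
            for b in ("<18", "18-64", ">=65")
        }
        for g, vals in (("cases", ages_c), ("non_cases", ages_nc))
    }
    stat, p = (None, None)
    if ages_c and ages_nc:
        stat, p = safe_chisq(
            [
                [band_counts["cases"][b] for b in ("<18", "18-64", ">=65")],
                [band_counts["non_cases"][b] for b in ("<18", "18-64", ">=65")],
            ]
        )
    add("age: <18", band_counts["cases"]["<18"], band_counts["non_cases"]["<18"],
        "pearson_chi2", stat, p)
    add("age: 18-64", band_counts["cases"]["18-64"], band_counts["non_cases"]["18-64"])
    add("age: >=65", band_counts["cases"][">=65"], band_counts["non_cases"][">=65"])
    add("age: missing", n_cases - len(ages_c), n_nc - len(ages_nc))

    # --- seriousness (serious vs not serious; "not available" excluded
    # from the test but shown with its share) ---
    ser = {
        g: {s: count(rep, lambda r, s=s: r.seriousness == s)
            for s in ("serious", "not_serious", "not_available")}
        for g, rep in (("cases", case_reports), ("non_cases", nc_reports))
    }
    stat, p = (None, None)
    if n_cases and n_nc:
        stat, p = safe_chisq(
            [
                [ser["cases"]["serious"], ser["cases"]["not_serious"]],
                [ser["non_cases"]["serious"], ser["non_cases"]["not_serious"]],
            ]
        )
    add("seriousness: serious", ser["cases"]["serious"], ser["non_cases"]["serious"],
        "pearson_chi2", stat, p)
    add("seriousness: not serious", ser["cases"]["not_serious"],
        ser["non_cases"]["not_serious"])
    add("seriousness: not available", ser["cases"]["not_available"],
        ser["non_cases"]["not_available"])
    for sub in ("medically_important", "hospitalization", "disability",
                "life_threatening", "death", "congenital_anomaly"):
        c_n = count(case_reports, lambda r, s=sub: r.serious_subtype == s)
        nc_n = count(nc_reports, lambda r, s=sub: r.serious_subtype == s)
        if c_n or nc_n:
            add(f"serious subtype: {sub}", c_n, nc_n)

    # --- outcomes: per-category binary tests (each outcome vs the other
    # known outcomes; missing excluded from testing) ---
    outcomes = ("complete_recovery", "improvement", "not_yet_recovered",
                "recovered_with_sequelae", "death")
    known_c = count(case_reports, lambda r: r.outcome != "missing")
    known_nc = count(nc_reports, lambda r: r.outcome != "missing")
    for out in outcomes:
        c_n = count(case_reports, lambda r, o=out: r.outcome == o)
        nc_n = count(nc_reports, lambda r, o=out: r.outcome == o)
        stat, p = (None, None)
        if known_c and known_nc:
            stat, p = safe_chisq(
                [[c_n, known_c - c_n], [nc_n, known_nc - nc_n]]
            )
        add(f"outcome: {out}", c_n, nc_n, "pearson_chi2", stat, p)
    add("outcome: missing", n_cases - known_c, n_nc - known_nc)

    # --- number of drugs ---
    nd_c = [r.n_drugs() for r in case_reports]
    nd_nc = [r.n_drugs() for r in nc_reports]
    stat, p = (None, None)
    if nd_c and nd_nc:
        stat, p = mann_whitney(nd_c, nd_nc)
    for name, vals in (("cases", nd_c), ("non_cases", nd_nc)):
        mi = _median_iqr(vals)
        V[f"median n_drugs ({name})"] = {
            "cases": None if mi is None else f"{mi[0]:g} ({mi[1]:g}-{mi[2]:g})",
            "cases_pct": None, "non_cases": None, "non_cases_pct": None,
            "test": "mann_whitney" if name == "cases" else None,
            "statistic": stat if name == "cases" else None,
            "p_value": p if name == "cases" else None,
        }

    # --- PT-group shares among cases ---
    canon_groups = {
        name: frozenset(pts) for name, pts in groups.items()
    }
    for name in canon_groups:
        c_n = count(case_reports, lambda r, n=name: bool(r.pts & canon_groups[n]))
        add(f"case PT group: {name}", c_n, 0)
        V[f"case PT group: {name}"]["non_cases"] = None
        V[f"case PT group: {name}"]["non_cases_pct"] = None

    return summary
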