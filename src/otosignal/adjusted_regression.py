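"""Adjusted reporting odds ratios via multivariable logistic regression.

Each drug-event pair gets its own model: case status regressed on the
0/1 exposure indicator plus age (years, continuous), sex (male = 1,
female reference) and the number of drugs on the report (suspected +
concomitant, continuous).  Covariates are pruned by backward elimination
on their Wald p-values at ``alpha_stay`` (5% by default); the exposure
term is never removed, since the model exists to estimate it.  The
adjusted ROR is ``exp`` of the exposure coefficient with a Wald CI.

Missing age or sex is handled by complete-case analysis.  Perfect
separation (a zero cell in the exposure x outcome cross-table) and
non-convergence are surfaced as errors, never silently patched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .case_classification import DEFAULT_EVENT_GROUPS, ClassifiedDatabase
from .disproportionality import (
    ANY_OTOTOXICITY,
    SignalResult,
    _group_case_ids,
    _report_exposed,
    SdrDecision,
)
from .errors import ConfigurationError, ConvergenceError, InsufficientDataError, SeparationError
from .srs_data import ReportDatabase, canonical

_ALLOWED_COVARIATES = ("age", "sex", "n_drugs")
#: fixed order used to break p-value ties during elimination
_COVARIATE_ORDER = {name: i for i, name in enumerate(_ALLOWED_COVARIATES)}

#: age bands available for the optional categorical age coding
AGE_BANDS = ((0, 18, "age_lt18"), (18, 65, "age_18_64"), (65, None, "age_ge65"))


@dataclass(frozen=True)
class AdjustmentSpec:
    covariates: tuple[str, ...] = _ALLOWED_COVARIATES
    alpha_stay: float = 0.05
    missing_policy: str = "complete_case"
    #: when True, age enters as <18 / 18-64 / >=65 dummies (18-64 reference)
    categorical_age: bool = False

    def __post_init__(self) -> None:
        if not self.covariates:
            # an empty covariate list is allowed only through the explicit
            # no-covariate constructor used in equivalence tests
            pass
        bad = [c for c in self.covariates if c not in _ALLOWED_COVARIATES]
        if bad:
            raise ConfigurationError(f"unknown covariates: {bad}")
        if not 0 < self.alpha_stay < 1:
            raise ConfigurationError("alpha_stay must be in (0, 1)")
        if self.missing_policy != "complete_case":
            raise ConfigurationError(
                f"unsupported missing policy: {self.missing_policy!r}"
            )


@dataclass(frozen=True)
class AdjustedEstimate:
    ror_adj: float
    ci_low: float
    ci_high: float
    retained_covariates: tuple[str, ...]
    n_used: int
    alpha: float = 0.05


def design_matrix(
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    drug_key: str,
    event_group: str = ANY_OTOTOXICITY,
    spec: AdjustmentSpec | None = None,
    groups: Mapping[str, Iterable[str]] | None = None,
    key_type: str = "substance",
    include_concomitant: bool = False,
) -> pd.DataFrame:
    """Model-ready table: one row per retained report.

    Columns: ``y`` (case indicator for the event group), ``exposure``
    (0/1), and the requested covariates.  Under complete-case analysis,
    rows missing a needed covariate are removed.
    """
    spec = spec or AdjustmentSpec()
    groups = groups or DEFAULT_EVENT_GROUPS
    key = drug_key.strip().upper() if key_type == "atc" else canonical(drug_key)
    case_ids = _group_case_ids(cls, db, event_group, groups)
    rows = []
    need_age = "age" in spec.covariates
    need_sex = "sex" in spec.covariates
    for rid, y in [(i, 1) for i in case_ids] + [(i, 0) for i in cls.non_cases]:
        r = db.by_id(rid)
        if need_age and r.age is None:
            continue
        if need_sex and r.sex == "unknown":
            continue
        rows.append(
            (
                y,
                int(_report_exposed(r, key, key_type, include_concomitant)),
                np.nan if r.age is None else r.age,
                {"male": 1, "female": 0}.get(r.sex, np.nan),
                r.n_drugs(),
            )
        )
    df = pd.DataFrame(rows, columns=["y", "exposure", "age", "sex", "n_drugs"])
    keep = ["y", "exposure"] + [c for c in spec.covariates]
    df = df[keep]
    if df.empty:
        raise InsufficientDataError(
            f"no usable rows for {drug_key}/{event_group} under "
            f"{spec.missing_policy}"
        )
    return df


def _expand_age(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Replace the continuous age column with band dummies (18-64 ref)."""
    out = df.drop(columns=["age"]).copy()
    out["age_lt18"] = (df["age"] < 18).astype(int)
    out["age_ge65"] = (df["age"] >= 65).astype(int)
    return out, {"age": ["age_lt18", "age_ge65"]}


def fit_adjusted(
    matrix: pd.DataFrame,
    spec: AdjustmentSpec | None = None,
    alpha: float = 0.05,
    maxiter: int = 100,
) -> AdjustedEstimate:
    """Backward-elimination logistic fit of ``y`` on exposure + covariates.

    Repeatedly removes the covariate with the largest Wald p-value above
    ``alpha_stay`` (ties broken by the fixed order age, sex, n_drugs)
    and refits until every remaining covariate is significant.  The
    exposure term is exempt from elimination.
    """
    spec = spec or AdjustmentSpec()
    if matrix["y"].nunique() < 2:
        raise InsufficientDataError("response has a single class")
    if matrix["exposure"].nunique() < 2:
        raise InsufficientDataError("exposure has a single level")
    xtab = pd.crosstab(matrix["exposure"], matrix["y"])
    if (xtab == 0).any().any() or xtab.shape != (2, 2):
        raise SeparationError(
            "exposure perfectly predicts case status (zero cell in the "
            "exposure x outcome cross-table)"
        )

    # covariate -> model column(s); categorical age maps to two dummies
    col_map: dict[str, list[str]] = {}
    work = matrix
    for cov in spec.covariates:
        col_map[cov] = [cov]
    if spec.categorical_age and "age" in spec.covariates:
        work, age_map = _expand_age(matrix)
        col_map.update(age_map)

    retained = list(spec.covariates)

    def _fit(covs: Sequence[str]):
        cols = ["exposure"] + [c for cov in covs for c in col_map[cov]]
        X = sm.add_constant(work[cols], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(work["y"], X).fit(disp=0, maxiter=maxiter)
        except PerfectSeparationError as exc:
            raise SeparationError(str(exc)) from exc
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                f"logistic fit did not converge in {maxiter} iterations"
            )
        return res

    res = _fit(retained)
    while retained:
        # Wald p per covariate; for multi-column covariates use the
        # smallest column p (the covariate stays if any dummy is needed)
        pvals = {
            cov: min(res.pvalues[c] for c in col_map[cov]) for cov in retained
        }
        worst = max(
            retained, key=lambda cov: (pvals[cov], -_COVARIATE_ORDER[cov])
        )
        if pvals[worst] <= spec.alpha_stay:
            break
        retained.remove(worst)
        res = _fit(retained)

    beta = res.params["exposure"]
    se = res.bse["exposure"]
    z = float(norm.ppf(1 - alpha / 2))
    return AdjustedEstimate(
        ror_adj=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        retained_covariates=tuple(retained),
        n_used=int(len(work)),
        alpha=alpha,
    )


def adjust_all(
    signals: list[SignalResult],
    cls: ClassifiedDatabase,
    db: ReportDatabase,
    spec: AdjustmentSpec | None = None,
    groups: Mapping[str, Iterable[str]] | None = None,
    min_reports: int = 3,
    alpha: float = 0.05,
    include_concomitant: bool = False,
) -> list[SignalResult]:
    """Attach adjusted estimates to each screened signal.

    Per-signal failures (separation, non-convergence, no usable rows) are
    recorded in ``fit_status`` and leave the crude fields intact; the run
    continues.  When adjustment succeeds, the SDR flag is re-evaluated on
    the adjusted CI.
    """
    spec = spec or AdjustmentSpec()
    for sig in signals:
        try:
            m = design_matrix(
                cls, db, sig.drug_key, sig.event_group, spec, groups,
                include_concomitant=include_concomitant,
            )
            est = fit_adjusted(m, spec, alpha=alpha)
        except SeparationError:
            sig.fit_status = "separation"
            continue
        except ConvergenceError:
            sig.fit_status = "convergence"
            continue
        except InsufficientDataError:
            sig.fit_status = "insufficient_data"
            continue
        sig.adjusted = est
        sig.fit_status = "ok"
        sig.sdr_adjusted = SdrDecision(
            is_sdr=(est.ci_low > 1.0) and (sig.table.a >= min_reports),
            n_reports=sig.table.a,
            rule=f"adjusted ci_low>1 and a>={min_reports}",
        )
    return signals
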