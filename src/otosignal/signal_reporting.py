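"""Pipeline orchestration, expectedness annotation and tabular outputs.

``run_pipeline`` executes the full chain — ingest (or simulate), dedup
and exclusions, case classification, crude screening, covariate
adjustment, expectedness annotation and cohort descriptives — from a
single YAML config, writing ``signals.csv``, ``signals_adjusted.csv``,
``cohort_summary.csv``, ``audit_log.tsv`` and ``run_manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .adjusted_regression import AdjustmentSpec, adjust_all
from .case_classification import (
    DEFAULT_EVENT_GROUPS,
    CaseDefinition,
    ClassifiedDatabase,
    default_case_definition,
    partition,
)
from .cohort_descriptives import summarize
from .disproportionality import ANY_OTOTOXICITY, SignalResult, screen
from .errors import OtosignalError
from .srs_data import (
    ReportDatabase,
    default_reference_labels,
    lookup_expectedness,
    read_pt_list,
    read_reference_labels,
    read_reports,
)

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "drug_key", "event_group", "a", "b", "c", "d",
    "ror", "ci_low", "ci_high", "corrected", "is_sdr",
]
ADJUSTED_COLUMNS = SIGNAL_COLUMNS + [
    "ror_adj", "ci_low_adj", "ci_high_adj", "retained_covariates",
    "n_used", "fit_status", "is_sdr_adjusted", "expectedness",
]


def annotate_expectedness(
    signals: list[SignalResult], labels: Mapping[tuple[str, str], str]
) -> list[SignalResult]:
    """Label every signal (SDR or not) against the reference labels."""
    for sig in signals:
        sig.expectedness = lookup_expectedness(
            labels, sig.drug_key, sig.event_group
        )
    return signals


def signals_to_frame(signals: Sequence[SignalResult],
                     adjusted: bool = True) -> pd.DataFrame:
    rows = []
    for s in signals:
        row = {
            "drug_key": s.drug_key,
            "event_group": s.event_group,
            "a": s.table.a, "b": s.table.b, "c": s.table.c, "d": s.table.d,
            "ror": s.crude.ror, "ci_low": s.crude.ci_low,
            "ci_high": s.crude.ci_high, "corrected": s.crude.corrected,
            "is_sdr": s.sdr.is_sdr,
        }
        if adjusted:
            est = s.adjusted
            row.update(
                {
                    "ror_adj": est.ror_adj if est else None,
                    "ci_low_adj": est.ci_low if est else None,
                    "ci_high_adj": est.ci_high if est else None,
                    "retained_covariates": (
                        "+".join(est.retained_covariates) if est else ""
                    ),
                    "n_used": est.n_used if est else None,
                    "fit_status": s.fit_status,
                    "is_sdr_adjusted": (
                        s.sdr_adjusted.is_sdr if s.sdr_adjusted else None
                    ),
                    "expectedness": s.expectedness,
                }
            )
        rows.append(row)
    cols = ADJUSTED_COLUMNS if adjusted else SIGNAL_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def _validate_output(path: Path, required_columns: Sequence[str]) -> None:
    df = pd.read_csv(path, nrows=5)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise OtosignalError(f"{path.name}: missing output columns {missing}")


def _load_database(cfg: dict, seed: int | None) -> ReportDatabase:
    inp = cfg.get("input", {})
    if inp.get("reports"):
        return read_reports(inp["reports"])
    if inp.get("fixture"):
        from .synthetic_srs import make_reference_fixture

        return make_reference_fixture()
    if "synthetic" in inp:
        from .synthetic_srs import SyntheticConfig, generate

        params = dict(inp["synthetic"] or {})
        if seed is not None:
            params["seed"] = seed
        return generate(SyntheticConfig(**params)).db
    raise OtosignalError(
        "config must provide input.reports, input.fixture or input.synthetic"
    )


def _case_definition(cfg: dict) -> CaseDefinition:
    cd_cfg = dict(cfg.get("case_definition", {}))
    pt_path = cfg.get("input", {}).get("pt_list")
    kwargs = {}
    if pt_path:
        kwargs["case_pts"] = read_pt_list(pt_path)
    for key in ("drop_pts", "exclude_sources", "exclude_atc_prefixes"):
        if key in cd_cfg:
            kwargs[key] = frozenset(cd_cfg[key])
    if "vertigo_policy" in cd_cfg:
        kwargs["vertigo_policy"] = cd_cfg["vertigo_policy"]
    if "case_pts" in kwargs:
        drop = kwargs.get("drop_pts", frozenset({"vertigo"}))
        kwargs["drop_pts"] = drop
        return default_case_definition(**kwargs)
    return default_case_definition(**kwargs)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> int:
    """Run the full pipeline from a YAML config; returns the exit status.

    Any stage error is logged with the stage name, partial outputs are
    removed and a nonzero status is returned.
    """
    config_path = Path(config_path)
    written: list[Path] = []
    stage = "config"
    try:
        if not config_path.exists():
            raise OtosignalError(f"config file not found: {config_path}")
        cfg = yaml.safe_load(config_path.read_text()) or {}
        seed = seed if seed is not None else cfg.get("seed")
        out = Path(out_dir or cfg.get("output_dir", "."))
        out.mkdir(parents=True, exist_ok=True)
        ana = cfg.get("analysis", {})
        min_reports = int(ana.get("min_reports", 3))
        alpha = float(ana.get("alpha", 0.05))
        do_adjust = bool(ana.get("adjust", True))
        groups = {
            k: frozenset(v) for k, v in ana.get("event_groups", {}).items()
        } or DEFAULT_EVENT_GROUPS
        event_groups = [ANY_OTOTOXICITY] + sorted(groups)

        stage = "ingest"
        db = _load_database(cfg, seed)
        n_ingested = len(db)
        logger.info("ingest: %d reports", n_ingested)

        lab_path = cfg.get("input", {}).get("reference_labels")
        labels = (
            read_reference_labels(lab_path) if lab_path
            else default_reference_labels()
        )

        stage = "classify"
        cd = _case_definition(cfg)
        dedup = ana.get("dedup", True)
        cls, db = partition(
            db, cd, dedup_key=_dedup_key_from_config(ana) if dedup else None
        )
        n_total = cls.n_cases + cls.n_non_cases + len(cls.dropped)
        assert n_total == n_ingested, "partition property violated"
        logger.info(
            "classify: %d cases, %d non-cases, %d dropped",
            cls.n_cases, cls.n_non_cases, len(cls.dropped),
        )

        audit_path = out / "audit_log.tsv"
        with audit_path.open("w") as fh:
            for rid, reason in cls.dropped.items():
                fh.write(f"{rid}\t{reason}\n")
        written.append(audit_path)

        stage = "screen"
        signals = screen(
            cls, db, event_groups=event_groups, groups=groups,
            min_reports=min_reports, alpha=alpha,
        )
        sig_path = out / "signals.csv"
        signals_to_frame(signals, adjusted=False).to_csv(sig_path, index=False)
        written.append(sig_path)
        _validate_output(sig_path, SIGNAL_COLUMNS)

        stage = "adjust"
        if do_adjust:
            spec = AdjustmentSpec(
                covariates=tuple(ana.get("covariates", ("age", "sex", "n_drugs"))),
                alpha_stay=float(ana.get("alpha_stay", 0.05)),
            )
            adjust_all(signals, cls, db, spec, groups=groups,
                       min_reports=min_reports, alpha=alpha)
        stage = "annotate"
        annotate_expectedness(signals, labels)
        adj_path = out / "signals_adjusted.csv"
        signals_to_frame(signals, adjusted=True).to_csv(adj_path, index=False)
        written.append(adj_path)
        _validate_output(adj_path, ADJUSTED_COLUMNS)

        stage = "describe"
        summary = summarize(cls, db, groups=groups)
        summary_path = out / "cohort_summary.csv"
        summary.to_frame().to_csv(summary_path, index=False)
        written.append(summary_path)
        _validate_output(summary_path, ["variable", "cases", "non_cases"])

        stage = "manifest"
        manifest = {
            "tool": "otosignal",
            "version": __version__,
            "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
            "seed": seed,
            "counts": {
                "ingested": n_ingested,
                "cases": cls.n_cases,
                "non_cases": cls.n_non_cases,
                "dropped": _reason_counts(cls.dropped),
                "signals": len(signals),
                "sdr_crude": sum(1 for s in signals if s.sdr.is_sdr),
            },
        }
        manifest_path = out / "run_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        written.append(manifest_path)
        return 0
    except Exception as exc:  # noqa: BLE001 — boundary: report and clean up
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        return 1


def _reason_counts(dropped: Mapping[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in dropped.values():
        counts[reason] = counts.get(reason, 0) + 1
    return counts


def _dedup_key_from_config(ana: dict) -> tuple[str, ...]:
    from .case_classification import DEFAULT_DEDUP_KEY

    return tuple(ana.get("dedup_key", DEFAULT_DEDUP_KEY))
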