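"""Adjusted ROR: design matrix, backward elimination, error surfacing."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from otosignal import (
    AdjustmentSpec,
    FocalDrug,
    SyntheticConfig,
    adjust_all,
    build_table,
    classify,
    crude_ror,
    default_case_definition,
    design_matrix,
    fit_adjusted,
    generate,
    partition,
    screen,
)
from otosignal.errors import ConfigurationError, InsufficientDataError, SeparationError

from conftest import make_db, make_report


def toy_classified():
    reports = []
    for i in range(5):
        reports.append(
            make_report(f"C{i}", pts=("tinnitus",), age=60 + i, sex="male",
                        drugs=(("drug x", None, "suspected"),
                               ("filler drug 001", None, "concomitant"),
                               ("filler drug 002", None, "concomitant")))
        )
    for i in range(5):
        reports.append(
            make_report(f"N{i}", age=40 + i,
                        drugs=(("filler drug 003", None, "suspected"),))
        )
    db = make_db(reports)
    return classify(db, default_case_definition()), db


class TestDesignMatrix:
    def test_n_drugs_counts_suspected_plus_concomitant(self):
        cls, db = toy_classified()
        m = design_matrix(cls, db, "drug x")
        assert set(m.columns) == {"y", "exposure", "age", "sex", "n_drugs"}
        assert m.loc[m["y"] == 1, "n_drugs"].unique().tolist() == [3]

    def test_toy_matrix_shape(self):
        cls, db = toy_classified()
        m = design_matrix(cls, db, "drug x")
        assert m.shape == (10, 5)  # y + exposure + 3 predictors

    def test_unknown_sex_dropped_under_complete_case(self):
        reports = [
            make_report("C1", pts=("tinnitus",), sex="unknown",
                        drugs=(("drug x", None, "suspected"),)),
            make_report("N1"),
        ]
        db = make_db(reports)
        cls = classify(db, default_case_definition())
        m = design_matrix(cls, db, "drug x")
        assert len(m) == 1  # the unknown-sex case is excluded

    def test_all_rows_removed_is_an_error(self):
        reports = [
            make_report("C1", pts=("tinnitus",), age=None,
                        drugs=(("drug x", None, "suspected"),)),
            make_report("N1", age=None),
        ]
        db = make_db(reports)
        cls = classify(db, default_case_definition())
        with pytest.raises(InsufficientDataError):
            design_matrix(cls, db, "drug x")

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ConfigurationError):
            AdjustmentSpec(covariates=("age", "height"))


class TestFitAdjusted:
    def test_separation_error_when_exposure_predicts_case(self):
        cls, db = toy_classified()  # every exposed report is a case
        m = design_matrix(cls, db, "drug x")
        with pytest.raises(SeparationError):
            fit_adjusted(m)

    def test_no_covariate_limit_equals_crude_ror(self):
        cfg = SyntheticConfig(
            n_reports=20_000, seed=13,
            focal_drugs=(FocalDrug("drug x", theta=math.log(3), gamma0=-2.2),),
            beta0=-3.0, beta_age=0.0,
            missing_age_rate=0, missing_sex_rate=0,
            dup_rate=0, literature_rate=0, vaccine_rate=0, bare_vertigo_rate=0,
        )
        res = generate(cfg)
        cls, db = partition(res.db, default_case_definition(), dedup_key=None)
        spec = AdjustmentSpec(covariates=())
        m = design_matrix(cls, db, "drug x", spec=spec)
        est = fit_adjusted(m, spec)
        crude = crude_ror(build_table(cls, db, "drug x"))
        assert abs(est.ror_adj - crude.ror) / crude.ror < 1e-6
        assert est.retained_covariates == ()

    def test_backward_elimination_is_deterministic(self):
        cfg = SyntheticConfig(
            n_reports=10_000, seed=17,
            focal_drugs=(FocalDrug("drug x", theta=math.log(2), gamma0=-2.0),),
            beta0=-3.0, beta_age=0.4,
            dup_rate=0, literature_rate=0, vaccine_rate=0, bare_vertigo_rate=0,
        )
        res = generate(cfg)
        cls, db = partition(res.db, default_case_definition(), dedup_key=None)
        m = design_matrix(cls, db, "drug x")
        e1 = fit_adjusted(m)
        e2 = fit_adjusted(m)
        assert e1 == e2
        assert "age" in e1.retained_covariates  # designed age effect stays

    def test_categorical_age_option(self):
        cfg = SyntheticConfig(
            n_reports=10_000, seed=18,
            focal_drugs=(FocalDrug("drug x", theta=math.log(2), gamma0=-2.0),),
            beta0=-3.0, beta_age=0.6,
            dup_rate=0, literature_rate=0, vaccine_rate=0, bare_vertigo_rate=0,
        )
        res = generate(cfg)
        cls, db = partition(res.db, default_case_definition(), dedup_key=None)
        spec = AdjustmentSpec(categorical_age=True)
        m = design_matrix(cls, db, "drug x", spec=spec)
        est = fit_adjusted(m, spec)
        assert est.ror_adj > 0


class TestAdjustAll:
    def test_empty_signal_list_unchanged(self):
        cls, db = toy_classified()
        assert adjust_all([], cls, db) == []

    def test_separation_recorded_with_crude_fields_intact(self):
        cls, db = toy_classified()
        signals = screen(cls, db, drug_universe=["drug x"], min_reports=1)
        adjust_all(signals, cls, db)
        (sig,) = signals
        assert sig.fit_status == "separation"
        assert sig.adjusted is None
        assert sig.crude.ror > 0

    def test_unconfounded_adjusted_and_crude_sdr_sets_match(self):
        cfg = SyntheticConfig(
            n_reports=30_000, seed=19,
            focal_drugs=(
                FocalDrug("signal drug", theta=math.log(6), gamma0=-3.0),
                FocalDrug("null drug", theta=0.0, gamma0=-3.0),
            ),
            beta0=-3.7, beta_age=0.0,
            dup_rate=0, literature_rate=0, vaccine_rate=0, bare_vertigo_rate=0,
        )
        res = generate(cfg)
        cls, db = partition(res.db, default_case_definition(), dedup_key=None)
        signals = screen(cls, db, drug_universe=["signal drug", "null drug"])
        adjust_all(signals, cls, db)
        for sig in signals:
            assert sig.fit_status == "ok"
            assert sig.sdr.is_sdr == sig.sdr_adjusted.is_sdr
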