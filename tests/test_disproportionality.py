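"""Crude ROR closed form, its regression equivalence, and SDR flagging."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from otosignal import (
    ContingencyTable,
    FocalDrug,
    RorEstimate,
    SyntheticConfig,
    build_table,
    classify,
    crude_ror,
    default_case_definition,
    flag_sdr,
    generate,
    partition,
    screen,
)
from otosignal.errors import DegenerateTableError

from conftest import make_db, make_report


def table(a, b, c, d):
    return ContingencyTable(a=a, b=b, c=c, d=d, drug_key="x")


def glm_log_odds_ratio(a, b, c, d):
    """Independent oracle: univariate logistic fit on the 2x2 counts."""
    import statsmodels.api as sm

    y = np.array([1, 1, 0, 0])
    x = sm.add_constant(np.array([1.0, 0.0, 1.0, 0.0]))
    w = np.array([a, c, b, d], dtype=float)
    res = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit()
    return float(res.params[1])


class TestCrudeRor:
    def test_amikacin_scale_table(self):
        est = crude_ror(table(16, 119, 636, 325209))
        assert est.ror == pytest.approx(68.75, abs=0.01)
        assert est.ci_low == pytest.approx(40.56, abs=0.05)
        assert est.ci_high == pytest.approx(116.53, abs=0.05)
        assert not est.corrected

    def test_balanced_table_is_exactly_one(self):
        assert crude_ror(table(5, 50, 5, 50)).ror == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        est = crude_ror(table(0, 2, 10, 20))
        assert est.corrected
        assert est.ror == pytest.approx((0.5 * 20.5) / (2.5 * 10.5), rel=1e-12)

    def test_error_policy_names_the_zero_cell(self):
        with pytest.raises(DegenerateTableError, match="a"):
            crude_ror(table(0, 2, 10, 20), zero_cell_policy="error")

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=500)] * 4)
    )
    def test_matches_univariate_logistic_slope(self, cells):
        a, b, c, d = cells
        est = crude_ror(table(a, b, c, d))
        expected = math.exp(glm_log_odds_ratio(a, b, c, d))
        assert abs(est.ror - expected) / expected < 1e-6

    @given(st.tuples(*[st.integers(min_value=1, max_value=300)] * 4))
    def test_label_swap_antisymmetry(self, cells):
        a, b, c, d = cells
        prod = crude_ror(table(a, b, c, d)).ror * crude_ror(table(b, a, d, c)).ror
        assert prod == pytest.approx(1.0, rel=1e-12)

    def test_increasing_a_increases_ror_and_ci_low(self):
        b, c, d = 40, 30, 900
        rors = [crude_ror(table(a, b, c, d)) for a in (3, 10, 30)]
        assert rors[0].ror < rors[1].ror < rors[2].ror
        assert rors[0].ci_low < rors[1].ci_low < rors[2].ci_low

    def test_scaling_cells_preserves_ror_and_narrows_ci(self):
        base = crude_ror(table(4, 40, 30, 900))
        scaled = crude_ror(table(40, 400, 300, 9000))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        assert scaled.ci_low > base.ci_low
        assert scaled.ci_high < base.ci_high


class TestSdrRule:
    @pytest.mark.parametrize(
        "ci_low,a,expected",
        [(1.2, 3, True), (0.9, 50, False), (2.0, 2, False)],
    )
    def test_threshold_rule(self, ci_low, a, expected):
        est = RorEstimate(ror=ci_low * 2, ci_low=ci_low, ci_high=ci_low * 4)
        t = table(a, 10, 100, 1000)
        assert flag_sdr(est, t, min_reports=3).is_sdr is expected


class TestBuildTableAndScreen:
    def _toy(self):
        reports = [
            make_report("C1", pts=("tinnitus",),
                        drugs=(("drug x", None, "suspected"),)),
            make_report("C2", pts=("hypoacusis",),
                        drugs=(("drug x", None, "suspected"),
                               ("drug x", "N02BA01", "concomitant"))),
            make_report("C3", pts=("tinnitus",),
                        drugs=(("drug y", None, "suspected"),)),
            make_report("N1", drugs=(("drug x", None, "suspected"),)),
            make_report("N2", drugs=(("drug y", None, "suspected"),)),
            make_report("N3", drugs=(("drug z", None, "suspected"),)),
        ]
        db = make_db(reports)
        cls = classify(db, default_case_definition())
        return cls, db

    def test_report_level_counting_and_dual_entry_counts_once(self):
        cls, db = self._toy()
        t = build_table(cls, db, "drug x")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_absent_drug_gives_zero_exposure_margins(self):
        cls, db = self._toy()
        t = build_table(cls, db, "absent drug")
        assert (t.a, t.b) == (0, 0)
        assert (t.c, t.d) == (3, 3)

    def test_event_group_restricts_case_margin(self):
        cls, db = self._toy()
        t = build_table(cls, db, "drug x", event_group="tinnitus")
        assert t.a + t.c == 2  # only the two tinnitus cases
        assert t.b + t.d == 3  # all non-cases

    def test_concomitant_exposure_switch(self):
        cls, db = self._toy()
        nar = build_table(cls, db, "drug x")
        wide = build_table(cls, db, "drug x", include_concomitant=True)
        assert wide.a >= nar.a

    def test_atc_prefix_key(self):
        cls, db = self._toy()
        t = build_table(cls, db, "N02", key_type="atc", include_concomitant=True)
        assert t.a == 1  # C2 via the concomitant ATC-coded entry

    def test_screen_flags_planted_association_only(self):
        cfg = SyntheticConfig(
            n_reports=30_000, seed=21,
            focal_drugs=(
                FocalDrug("guilty drug", theta=math.log(10), gamma0=-4.0),
                FocalDrug("innocent drug", theta=0.0, gamma0=-4.0),
            ),
            beta0=-4.6, beta_age=0.0,
            dup_rate=0, literature_rate=0, vaccine_rate=0, bare_vertigo_rate=0,
        )
        res = generate(cfg)
        cls, db = partition(res.db, default_case_definition(), dedup_key=None)
        signals = screen(cls, db, drug_universe=["guilty drug", "innocent drug"])
        by_name = {s.drug_key: s for s in signals}
        assert by_name["guilty drug"].sdr.is_sdr
        assert not by_name["innocent drug"].sdr.is_sdr

    def test_min_reports_filters_universe(self):
        cls, db = self._toy()
        assert screen(cls, db, min_reports=3) == []
        some = screen(cls, db, min_reports=1)
        assert [s.drug_key for s in some][:2] == ["drug x", "drug y"]

    def test_ordering_descending_a_then_key(self, ):
        cls, db = self._toy()
        sigs = screen(cls, db, min_reports=1)
        keys = [(-(s.table.a), s.drug_key) for s in sigs]
        assert keys == sorted(keys)
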