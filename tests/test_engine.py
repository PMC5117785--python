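import math

import numpy as np
import pytest

import cervimpact as cv
from cervimpact import engine
from cervimpact import tables as T


def two_stage_tables():
    """A small instance solvable by direct spreadsheet-style arithmetic."""
    counts = T.CaseCountTable(
        {
            ("35-64", "1B", "not_screened"): 50.0,
            ("35-64", "1B", "regular"): 40.0,
            ("35-64", "3plus", "not_screened"): 30.0,
            ("35-64", "3plus", "regular"): 10.0,
        }
    )
    ors = T.ORTable(
        {
            ("35-64", "1B", "not_screened"): T.REFERENT_CELL,
            ("35-64", "1B", "regular"): T.ORCell(0.4, 0.3, 0.55, 0.15),
            ("35-64", "3plus", "not_screened"): T.REFERENT_CELL,
            ("35-64", "3plus", "regular"): T.ORCell(0.1, 0.05, 0.2, 0.3),
        }
    )
    fatality = T.FatalityTable(
        {("35-64", "1A"): 0.02, ("35-64", "1B"): 0.1, ("35-64", "3plus"): 0.8}
    )
    return counts, ors, fatality


class TestCounterfactualCancers:
    def test_single_cell_halved_or_doubles(self):
        counts = T.CaseCountTable({("35-64", "2", "regular"): 100.0})
        ors = T.ORTable({("35-64", "2", "regular"): T.ORCell(0.5, 0.4, 0.6, 0.1)})
        out = cv.counterfactual_cancers(counts, ors, "no_screening")
        assert out.get("35-64", "2", "not_screened") == pytest.approx(200.0)

    def test_all_or_one_is_conservation(self, fixture_tables):
        counts = cv.reallocate_missing(fixture_tables[0])
        unit = T.ORTable({k: T.REFERENT_CELL for k in counts.entries})
        out = cv.counterfactual_cancers(counts, unit, "no_screening")
        for band in counts.bands():
            for stage in counts.stages(band):
                assert out.stage_total(band, stage) == pytest.approx(
                    counts.stage_total(band, stage)
                )

    def test_all_regular_scenario(self):
        counts, ors, _ = two_stage_tables()
        out = cv.counterfactual_cancers(counts, ors, "all_regular")
        # 1B absent screening: 50 + 40/0.4 = 150; times OR_regular 0.4 = 60
        assert out.get("35-64", "1B", "regular") == pytest.approx(60.0)

    def test_missing_or_for_occupied_cell_is_error(self):
        counts = T.CaseCountTable({("35-64", "2", "irregular"): 5.0})
        with pytest.raises(ValueError, match="no OR"):
            cv.counterfactual_cancers(counts, T.ORTable({}), "no_screening")


class TestExcessDeaths:
    def test_plain_product(self):
        counts = T.CaseCountTable({("35-64", "2", "regular"): 100.0})
        fat = T.FatalityTable({("35-64", "2"): 0.1})
        assert cv.excess_deaths(counts, fat)["35-64"] == pytest.approx(10.0)

    def test_stage_1a_substitution_for_never_screened(self):
        counts = T.CaseCountTable({("35-49", "1A", "not_screened"): 100.0})
        fat = T.FatalityTable({("35-49", "1A"): 0.014, ("35-49", "1B"): 0.086})
        sub = cv.excess_deaths(counts, fat, cv.Scenario("current", "substitute_1b"))
        keep = cv.excess_deaths(counts, fat, cv.Scenario("current", "keep_1a"))
        assert sub["35-49"] == pytest.approx(8.6)
        assert keep["35-49"] == pytest.approx(1.4)
        assert keep["35-49"] < sub["35-49"]

    def test_screened_1a_keeps_its_own_fatality(self):
        counts = T.CaseCountTable({("35-49", "1A", "regular"): 100.0})
        fat = T.FatalityTable({("35-49", "1A"): 0.014, ("35-49", "1B"): 0.086})
        assert cv.excess_deaths(counts, fat)["35-49"] == pytest.approx(1.4)


class TestIndirectRR:
    def test_referent_category_is_exactly_one(self):
        counts, ors, fat = two_stage_tables()
        rr = cv.indirect_rr(counts, ors, fat, "mortality", T.NOT_SCREENED, "35-64")
        assert (rr.rr, rr.lo, rr.hi) == (1.0, 1.0, 1.0)

    def test_matches_spreadsheet_arithmetic(self):
        counts, ors, fat = two_stage_tables()
        inc = cv.indirect_rr(counts, ors, None, "incidence", "regular", "35-64")
        num = 40.0 + 10.0
        den = 40.0 / 0.4 + 10.0 / 0.1
        assert inc.rr == pytest.approx(num / den, rel=1e-12)
        w1, w3 = (40 / 0.4) / den, (10 / 0.1) / den
        assert inc.var_log == pytest.approx(w1**2 * 0.15**2 + w3**2 * 0.3**2, rel=1e-12)

        mort = cv.indirect_rr(counts, ors, fat, "mortality", "regular", "35-64")
        mnum = 40.0 * 0.1 + 10.0 * 0.8
        mden = 40.0 / 0.4 * 0.1 + 10.0 / 0.1 * 0.8
        assert mort.rr == pytest.approx(mnum / mden, rel=1e-12)

    def test_incidence_rr_between_stage_or_extremes(self, imputed):
        counts, ors, fat, _ = imputed
        for band in counts.bands():
            for cat in (T.REGULAR, T.IRREGULAR):
                rr = cv.indirect_rr(counts, ors, None, "incidence", cat, band)
                cells = [
                    ors.get(band, s, cat).odds_ratio
                    for s in counts.stages(band)
                    if ors.has(band, s, cat)
                ]
                assert min(cells) - 1e-12 <= rr.rr <= max(cells) + 1e-12

    def test_mortality_not_above_incidence_on_monotone_tables(self, imputed):
        """Screening shifts stage, so its mortality benefit exceeds its
        incidence benefit whenever ORs fall and fatality rises with stage."""
        counts, ors, fat, _ = imputed
        for band in ("35-64",):
            for cat in (T.REGULAR, T.IRREGULAR, T.VERY_IRREGULAR):
                inc = cv.indirect_rr(counts, ors, fat, "incidence", cat, band)
                mort = cv.indirect_rr(counts, ors, fat, "mortality", cat, band)
                assert mort.rr <= inc.rr + 1e-12

    def test_empty_band_is_error(self):
        counts, ors, fat = two_stage_tables()
        with pytest.raises(ValueError, match="no cells"):
            cv.indirect_rr(counts, ors, fat, "mortality", "regular", "65-79")


class TestScenarioMortalityRR:
    def test_hand_computed_ratio(self):
        counts, ors, fat = two_stage_tables()
        rr = cv.scenario_mortality_rr(counts, ors, fat, "35-64", "no_screening")
        current = (50 + 40) * 0.1 + (30 + 10) * 0.8
        absent = (50 + 40 / 0.4) * 0.1 + (30 + 10 / 0.1) * 0.8
        assert rr.rr == pytest.approx(absent / current, rel=1e-12)

    def test_regular_scenario_reduces_mortality(self, imputed):
        counts, ors, fat, _ = imputed
        for band in counts.bands():
            ns = cv.scenario_mortality_rr(counts, ors, fat, band, "no_screening")
            reg = cv.scenario_mortality_rr(counts, ors, fat, band, "all_regular")
            assert ns.rr > 1.0 > reg.rr
            assert ns.lo <= ns.rr <= ns.hi


class TestDeathsPrevented:
    def test_single_band_doubling(self):
        observed = T.ObservedDeaths({"40-54": 100.0}, all_ages=100.0)
        rrs = {
            "35-49": {
                "no_screening": engine.RRWithCI.from_var(2.0, 0.0),
                "all_regular": engine.RRWithCI.from_var(0.5, 0.0),
            }
        }
        rep = cv.deaths_prevented(rrs, observed)
        assert rep.total_no_screening.rr == pytest.approx(200.0)
        assert rep.additional_no_screening == pytest.approx(100.0)
        assert rep.further_preventable == pytest.approx(50.0)
        assert rep.fraction_currently_prevented.rr == pytest.approx(0.5)
        assert rep.fraction_preventable.rr == pytest.approx(0.75)

    def test_death_band_shift(self):
        assert engine.death_band_label("35-49") == "40-54"
        assert engine.death_band_label("50-64") == "55-69"
        assert engine.death_band_label("65-79") == "70-84"
        assert engine.death_band_label("25-34") == "25-39"

    def test_band_mismatch_is_error(self):
        observed = T.ObservedDeaths({"25-39": 10.0}, all_ages=10.0)
        rrs = {"50-64": {"no_screening": engine.RRWithCI.from_var(2.0, 0.0),
                         "all_regular": engine.RRWithCI.from_var(0.5, 0.0)}}
        with pytest.raises(ValueError, match="missing"):
            cv.deaths_prevented(rrs, observed)

    def test_out_of_band_deaths_held_constant(self):
        observed = T.ObservedDeaths({"40-54": 100.0}, all_ages=150.0)
        rrs = {"35-49": {"no_screening": engine.RRWithCI.from_var(3.0, 0.0),
                         "all_regular": engine.RRWithCI.from_var(0.5, 0.0)}}
        rep = cv.deaths_prevented(rrs, observed)
        assert rep.total_no_screening.rr == pytest.approx(300 + 50)
        assert rep.total_all_regular.rr == pytest.approx(50 + 50)


class TestDeltaVsBootstrap:
    def test_delta_ci_close_to_parametric_bootstrap(self, imputed):
        counts, ors, fat, _ = imputed
        delta = cv.indirect_rr(counts, ors, fat, "mortality", T.REGULAR, "35-64")
        lo, hi = cv.bootstrap_rr_ci(
            counts, ors, fat, "mortality", T.REGULAR, "35-64", n_reps=4000, seed=123
        )
        assert delta.lo == pytest.approx(lo, rel=0.10)
        assert delta.hi == pytest.approx(hi, rel=0.10)
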