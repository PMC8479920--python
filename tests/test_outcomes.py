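"""Prevented/postponed accounting, discounting, currency, rounding, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodiumsim.engine import EventLedger
from sodiumsim.outcomes import (
    CostParams,
    cost_savings,
    discount,
    prevented_or_postponed,
    render_cost_results,
    render_results,
    round_sig,
    to_usd,
)


def toy_ledger(values: dict, years=(2013, 2014, 2015)) -> EventLedger:
    ledger = EventLedger(list(years))
    for (year, sex, band, col), v in values.items():
        ledger.table.loc[(year, sex, band), col] = v
    return ledger


class TestPreventedOrPostponed:
    def test_identical_ledgers_give_zeros(self):
        a = toy_ledger({(2013, 0, 1, "case_years_chd"): 5.0})
        b = toy_ledger({(2013, 0, 1, "case_years_chd"): 5.0})
        diff = prevented_or_postponed(a, b, "cases")
        assert (diff == 0).all().all()

    def test_simple_subtraction(self):
        a = toy_ledger({(2014, 1, 2, "case_years_stroke"): 10.0})
        b = toy_ledger({(2014, 1, 2, "case_years_stroke"): 7.0})
        diff = prevented_or_postponed(a, b, "cases")
        assert diff.loc[(2014, 1, 2), "stroke"] == 3.0
        assert diff["chd"].sum() == 0.0

    def test_two_person_three_year_hand_enumeration(self):
        # person A (male, 50s): CHD incident 2013, lives 3 years with it under
        # baseline; under policy incident 2014, lives 2 years. person B
        # (female, 60s): stroke incident 2014 baseline only (prevented).
        base = toy_ledger(
            {
                (2013, 0, 2, "case_years_chd"): 1.0,
                (2014, 0, 2, "case_years_chd"): 1.0,
                (2015, 0, 2, "case_years_chd"): 1.0,
                (2014, 1, 3, "case_years_stroke"): 1.0,
                (2015, 1, 3, "case_years_stroke"): 1.0,
            }
        )
        pol = toy_ledger(
            {
                (2014, 0, 2, "case_years_chd"): 1.0,
                (2015, 0, 2, "case_years_chd"): 1.0,
            }
        )
        diff = prevented_or_postponed(base, pol, "cases")
        assert diff["chd"].sum() == 1.0  # one CHD case-year postponed away
        assert diff["stroke"].sum() == 2.0  # both stroke case-years prevented
        assert diff.loc[(2013, 0, 2), "chd"] == 1.0
        assert diff.loc[(2014, 0, 2), "chd"] == 0.0

    def test_mismatched_strata_rejected(self):
        a = toy_ledger({}, years=(2013, 2014))
        b = toy_ledger({}, years=(2013, 2014, 2015))
        with pytest.raises(ValueError, match="mismatched"):
            prevented_or_postponed(a, b, "cases")

    def test_unknown_measure_rejected(self):
        a = toy_ledger({})
        with pytest.raises(KeyError):
            prevented_or_postponed(a, a, "qalys")


class TestDiscounting:
    def test_base_year_unchanged(self):
        assert discount(100.0, 2013, CostParams()) == pytest.approx(100.0)

    def test_one_and_ten_year_factors(self):
        p = CostParams()
        assert discount(100.0, 2014, p) == pytest.approx(97.087, abs=1e-3)
        assert discount(100.0, 2023, p) == pytest.approx(74.409, abs=1e-3)

    def test_year_before_base_rejected(self):
        with pytest.raises(ValueError):
            discount(100.0, 2012, CostParams())

    def test_discounted_never_exceeds_nominal(self):
        p = CostParams()
        years = np.arange(2013, 2033)
        d = discount(np.full(20, 50.0), years, p)
        assert np.all(d <= 50.0)
        assert d.sum() < 20 * 50.0


class TestCurrency:
    @pytest.mark.parametrize("brl,usd", [(3.876, 1.0), (0.0, 0.0), (387.6, 100.0)])
    def test_exchange_rate(self, brl, usd):
        assert to_usd(brl, CostParams()) == pytest.approx(usd)


class TestCostSavings:
    def _diff(self, chd=0.0, stroke=0.0, year=2013, sex=0):
        idx = pd.MultiIndex.from_product(
            [[2013, 2014], [0, 1], range(6)], names=["year", "sex", "age_band"]
        )
        df = pd.DataFrame(0.0, index=idx, columns=["chd", "stroke"])
        df.loc[(year, sex, 2), "chd"] = chd
        df.loc[(year, sex, 2), "stroke"] = stroke
        return df

    def test_zero_case_years_zero_savings(self):
        out = cost_savings(self._diff(), CostParams())
        assert out.savings_brl.sum() == 0.0

    def test_hand_computed_base_year_savings(self):
        # 100 CHD case-years x R$3876/case-year in the base year = US$100k
        params = CostParams(
            hospitalisation={"chd": 2000.0, "stroke": 0.0},
            ambulatory={"chd": 1876.0, "stroke": 0.0},
            informal={"chd": 0.0, "stroke": 0.0},
        )
        out = cost_savings(self._diff(chd=100.0), params)
        sus = out[(out.disease == "chd") & (out.component == "sus_medical")]
        assert sus.savings_brl.sum() == pytest.approx(387_600.0)
        assert sus.savings_usd.sum() == pytest.approx(100_000.0)

    def test_component_additivity(self):
        out = cost_savings(self._diff(chd=10.0, stroke=4.0), CostParams())
        total = out.savings_brl.sum()
        by_component = out.groupby("component").savings_brl.sum()
        by_disease = out.groupby("disease").savings_brl.sum()
        assert by_component.sum() == pytest.approx(total)
        assert by_disease.sum() == pytest.approx(total)

    def test_missing_unit_cost_rejected(self):
        params = CostParams(hospitalisation={"chd": 100.0})  # stroke missing
        with pytest.raises(ValueError, match="stroke"):
            cost_savings(self._diff(chd=1.0), params)

    def test_discounting_applied_per_year(self):
        params = CostParams(
            hospitalisation={"chd": 1000.0, "stroke": 0.0},
            ambulatory={"chd": 0.0, "stroke": 0.0},
            informal={"chd": 0.0, "stroke": 0.0},
        )
        out = cost_savings(self._diff(chd=1.0, year=2014), params)
        sus = out[(out.disease == "chd") & (out.component == "sus_medical")]
        assert sus.savings_brl.sum() == pytest.approx(1000.0 / 1.03)


class TestRoundSig:
    @pytest.mark.parametrize(
        "raw,rounded",
        [
            (182_000, 180_000),  # published "some 180,000 CVD cases"
            (14_100, 14_000),
            (0.196, 0.20),
            (0.0, 0.0),
            (98_400, 98_000),
            (985, 990),
            (-2_450, -2_500),
        ],
    )
    def test_two_significant_digits(self, raw, rounded):
        assert round_sig(raw) == pytest.approx(rounded)

    @given(
        mantissa=st.floats(min_value=1.0, max_value=9.99),
        k=st.integers(min_value=-3, max_value=6),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_scale_invariance(self, mantissa, k):
        assert round_sig(mantissa * 10.0**k) == pytest.approx(
            round_sig(mantissa) * 10.0**k, rel=1e-9
        )


class TestRenderResults:
    def _diffs(self, chd_m=67_000.0, chd_f=31_000.0):
        idx = pd.MultiIndex.from_product(
            [[2013], [0, 1], range(6)], names=["year", "sex", "age_band"]
        )
        cases = pd.DataFrame(0.0, index=idx, columns=["chd", "stroke"])
        deaths = pd.DataFrame(0.0, index=idx, columns=["chd", "stroke", "other"])
        cases.loc[(2013, 0, 2), "chd"] = chd_m
        cases.loc[(2013, 1, 2), "chd"] = chd_f
        return cases, deaths

    def test_persons_equals_men_plus_women(self):
        cases, deaths = self._diffs()
        table = render_results(cases, deaths)
        row = table[table.key == "chd_cases"].iloc[0]
        assert row.persons_raw == row.men_raw + row.women_raw == 98_000.0
        assert row.persons == 98_000.0

    def test_all_zero_differences_all_zero_table(self):
        cases, deaths = self._diffs(0.0, 0.0)
        table = render_results(cases, deaths)
        assert (table[["men_raw", "women_raw", "persons_raw"]] == 0).all().all()

    def test_percentage_of_total_with_two_sig_digits(self):
        cases, deaths = self._diffs(1.0, 0.0)
        table = render_results(cases, deaths, {"chd_cases": 1000.0})
        row = table[table.key == "chd_cases"].iloc[0]
        assert row.pct_of_total == pytest.approx(0.10)

    def test_zero_denominator_gives_absent_percentage(self):
        cases, deaths = self._diffs()
        table = render_results(cases, deaths, {"chd_cases": 0.0})
        row = table[table.key == "chd_cases"].iloc[0]
        assert np.isnan(row.pct_of_total)

    def test_cost_table_components_sum_to_totals(self):
        idx = pd.MultiIndex.from_product(
            [[2013], [0, 1], range(6)], names=["year", "sex", "age_band"]
        )
        diff = pd.DataFrame(1.0, index=idx, columns=["chd", "stroke"])
        savings = cost_savings(diff, CostParams())
        table = render_cost_results(savings).set_index("key")
        total = table.loc["total", "persons_raw"]
        assert table.loc["sus_total", "persons_raw"] + table.loc[
            "informal_total", "persons_raw"
        ] == pytest.approx(total)
        assert table.loc["chd_total", "persons_raw"] + table.loc[
            "stroke_total", "persons_raw"
        ] == pytest.approx(total)
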