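"""Cases/deaths prevented or postponed and discounted cost savings.

A "case prevented or postponed" is accounted as a case-year: one person
living one year with prevalent CHD or stroke. Annual treatment costs attach
to case-years (public-system medical costs plus informal, non-medical
caregiving costs), are discounted at 3%/year to the horizon start, and are
reported in Brazilian Reals and US dollars (R$3.876 per US$). Published
tables round to 2 significant digits; all internal arithmetic stays on raw
values and rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .engine import EventLedger
from .population import SEX_FEMALE, SEX_MALE

__all__ = [
    "CostParams",
    "prevented_or_postponed",
    "discount",
    "to_usd",
    "cost_savings",
    "round_sig",
    "render_results",
    "render_cost_results",
]

BRL_PER_USD = 3.876

DISEASES = ("chd", "stroke")
COST_COMPONENTS = ("sus_medical", "informal")

MEASURE_COLUMNS = {
    "cases": {"chd": "case_years_chd", "stroke": "case_years_stroke"},
    "deaths": {"chd": "deaths_chd", "stroke": "deaths_stroke", "other": "deaths_other"},
    "incidence": {"chd": "incident_chd", "stroke": "incident_stroke"},
}


@dataclass
class CostParams:
    """Annual unit costs (BRL per prevalent case-year) and discounting.

    ``hospitalisation`` reflects public-system (SUS) inpatient tables;
    ``ambulatory`` bundles primary care, outpatient visits and medication;
    ``informal`` is non-medical caregiving (extrapolated from EU estimates,
    a known limitation). SUS medical cost = hospitalisation + ambulatory.
    """

    hospitalisation: dict = field(default_factory=lambda: {"chd": 1100.0, "stroke": 1350.0})
    ambulatory: dict = field(default_factory=lambda: {"chd": 1450.0, "stroke": 1100.0})
    informal: dict = field(default_factory=lambda: {"chd": 820.0, "stroke": 1250.0})
    discount_rate: float = 0.03
    discount_base_year: int = 2013
    brl_per_usd: float = BRL_PER_USD

    def validate(self) -> None:
        problems = []
        for name in ("hospitalisation", "ambulatory", "informal"):
            table = getattr(self, name)
            for d in DISEASES:
                if d not in table:
                    problems.append(f"missing {name} unit cost for disease '{d}'")
                elif table[d] < 0:
                    problems.append(f"{name}[{d}] must be >= 0")
        if not (0.0 <= self.discount_rate < 1.0):
            problems.append("discount_rate must lie in [0, 1)")
        if self.brl_per_usd <= 0:
            problems.append("brl_per_usd must be > 0")
        if problems:
            raise ValueError("; ".join(problems))

    def sus_unit_cost(self, disease: str) -> float:
        return self.hospitalisation[disease] + self.ambulatory[disease]

    def unit_cost(self, disease: str, component: str) -> float:
        if component == "sus_medical":
            return self.sus_unit_cost(disease)
        if component == "informal":
            return self.informal[disease]
        raise KeyError(f"unknown cost component '{component}'")


def prevented_or_postponed(
    baseline: EventLedger, policy: EventLedger, measure: str = "cases"
) -> pd.DataFrame:
    """Stratified baseline - policy differences for one outcome measure.

    ``measure``: 'cases' (case-years of prevalent disease), 'deaths'
    (death counts by cause) or 'incidence' (first events). Returns a frame
    indexed by (year, sex, age_band) with one column per disease/cause.
    Ledgers must come from one common-random-numbers pair (same strata).
    """
    if measure not in MEASURE_COLUMNS:
        raise KeyError(f"unknown measure '{measure}'")
    if not baseline.table.index.equals(policy.table.index):
        raise ValueError("ledgers have mismatched strata")
    cols = MEASURE_COLUMNS[measure]
    diff = pd.DataFrame(index=baseline.table.index)
    for key, col in cols.items():
        diff[key] = baseline.table[col] - policy.table[col]
    return diff


def discount(amount, year: int, params: CostParams):
    """Present value of ``amount`` incurred in ``year`` at the configured rate."""
    if np.any(np.asarray(year) < params.discount_base_year):
        raise ValueError("year precedes the discount base year")
    factor = (1.0 + params.discount_rate) ** (
        np.asarray(year, dtype=float) - params.discount_base_year
    )
    out = np.asarray(amount, dtype=float) / factor
    return out if out.ndim else float(out)


def to_usd(amount_brl, params: CostParams):
    """Convert BRL to USD at the fixed configured exchange rate."""
    out = np.asarray(amount_brl, dtype=float) / params.brl_per_usd
    return out if out.ndim else float(out)


def cost_savings(case_year_differences: pd.DataFrame, params: CostParams) -> pd.DataFrame:
    """Discounted cost savings from case-years prevented or postponed.

    ``case_year_differences`` is the output of
    :func:`prevented_or_postponed` with measure='cases' (indexed by year,
    sex, age_band, one column per disease). Savings per disease, component
    and sex = sum over years of case-years * annual unit cost, discounted to
    the base year. Returns a tidy frame with columns disease, component,
    sex, savings_brl, savings_usd; component additivity is exact.
    """
    params.validate()
    df = case_year_differences.reset_index()
    missing = [d for d in DISEASES if d not in df.columns]
    if missing:
        raise KeyError(f"missing case-year columns for disease(s): {missing}")
    rows = []
    for disease in DISEASES:
        for component in COST_COMPONENTS:
            unit = params.unit_cost(disease, component)
            for sex in (SEX_MALE, SEX_FEMALE):
                sub = df[df.sex == sex]
                raw = sub[disease].to_numpy() * unit
                disc = discount(raw, sub.year.to_numpy(), params)
                brl = float(np.sum(disc))
                rows.append(
                    {
                        "disease": disease,
                        "component": component,
                        "sex": sex,
                        "savings_brl": brl,
                        "savings_usd": to_usd(brl, params),
                    }
                )
    return pd.DataFrame(rows)


def round_sig(value, digits: int = 2):
    """Round to ``digits`` significant digits, half away from zero.

    Presentation-only: 182000 -> 180000, 14100 -> 14000, 0.196 -> 0.20.
    Zero stays zero.
    """
    value = np.asarray(value, dtype=float)

    def _one(v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("round_sig requires finite values")
        if v == 0.0:
            return 0.0
        exponent = int(np.floor(np.log10(abs(v))))
        quantum = Decimal(1).scaleb(exponent - digits + 1)
        return float(Decimal(repr(v)).quantize(quantum, rounding=ROUND_HALF_UP))

    if value.ndim == 0:
        return _one(float(value))
    return np.vectorize(_one)(value)


ROW_ORDER = [
    ("chd_cases", "CHD cases prevented or postponed"),
    ("stroke_cases", "Stroke cases prevented or postponed"),
    ("chd_deaths", "CHD deaths prevented or postponed"),
    ("stroke_deaths", "Stroke deaths prevented or postponed"),
    ("noncvd_deaths", "Non-CVD deaths prevented or postponed"),
    ("all_deaths", "All deaths prevented or postponed"),
]


def render_results(
    case_diff: pd.DataFrame,
    death_diff: pd.DataFrame,
    baseline_totals: dict | None = None,
) -> pd.DataFrame:
    """Assemble the headline health-outcome table (men/women/persons).

    ``case_diff``/``death_diff`` come from :func:`prevented_or_postponed`
    (measures 'cases' and 'deaths'). ``baseline_totals`` maps row keys to
    baseline-scenario cumulative totals used as percent-of-total
    denominators; zero or missing denominators yield an absent percentage
    rather than infinity. Raw values sit beside 2-significant-digit rounded
    ones; persons = men + women on raw values.
    """

    def by_sex(diff: pd.DataFrame, col: str) -> tuple[float, float]:
        sums = diff.groupby(level="sex")[col].sum()
        return float(sums.get(SEX_MALE, 0.0)), float(sums.get(SEX_FEMALE, 0.0))

    values = {}
    values["chd_cases"] = by_sex(case_diff, "chd")
    values["stroke_cases"] = by_sex(case_diff, "stroke")
    values["chd_deaths"] = by_sex(death_diff, "chd")
    values["stroke_deaths"] = by_sex(death_diff, "stroke")
    values["noncvd_deaths"] = by_sex(death_diff, "other")
    values["all_deaths"] = tuple(
        values["chd_deaths"][i] + values["stroke_deaths"][i] + values["noncvd_deaths"][i]
        for i in (0, 1)
    )

    rows = []
    for key, label in ROW_ORDER:
        men, women = values[key]
        persons = men + women
        denom = (baseline_totals or {}).get(key)
        if denom:
            pct = 100.0 * persons / denom
            pct_rounded = round_sig(pct)
        else:
            pct = pct_rounded = np.nan
        rows.append(
            {
                "outcome": label,
                "key": key,
                "men_raw": men,
                "women_raw": women,
                "persons_raw": persons,
                "men": round_sig(men),
                "women": round_sig(women),
                "persons": round_sig(persons),
                "pct_of_total_raw": pct,
                "pct_of_total": pct_rounded,
            }
        )
    return pd.DataFrame(rows)


def render_cost_results(savings: pd.DataFrame, baseline_cost_total: float | None = None) -> pd.DataFrame:
    """Assemble the cost table (USD millions) mirroring the impact inventory.

    Rows: total change, SUS medical and informal components, and per-disease
    splits; columns men/women/persons, raw and rounded. ``savings`` is the
    tidy output of :func:`cost_savings`.
    """
    usd_m = savings.copy()
    usd_m["usd_millions"] = usd_m["savings_usd"] / 1e6

    def cell(mask) -> tuple[float, float]:
        sub = usd_m[mask]
        men = float(sub.loc[sub.sex == SEX_MALE, "usd_millions"].sum())
        women = float(sub.loc[sub.sex == SEX_FEMALE, "usd_millions"].sum())
        return men, women

    spec_rows = [
        ("total", "Change in total health-related costs", np.ones(len(usd_m), dtype=bool)),
        ("sus_total", "Total medical costs to SUS", usd_m.component == "sus_medical"),
        ("informal_total", "Total informal care costs", usd_m.component == "informal"),
    ]
    for disease in DISEASES:
        name = disease.upper() if disease == "chd" else disease.capitalize()
        spec_rows += [
            (f"{disease}_total", f"Total {name}-related costs", usd_m.disease == disease),
            (
                f"{disease}_sus",
                f"{name} medical costs to SUS",
                (usd_m.disease == disease) & (usd_m.component == "sus_medical"),
            ),
            (
                f"{disease}_informal",
                f"Informal care {name} costs",
                (usd_m.disease == disease) & (usd_m.component == "informal"),
            ),
        ]
    rows = []
    for key, label, mask in spec_rows:
        men, women = cell(mask)
        persons = men + women
        if baseline_cost_total:
            pct = 100.0 * persons / baseline_cost_total
            pct_rounded = round_sig(pct)
        else:
            pct = pct_rounded = np.nan
        rows.append(
            {
                "outcome": label,
                "key": key,
                "men_raw": men,
                "women_raw": women,
                "persons_raw": persons,
                "men": round_sig(men),
                "women": round_sig(women),
                "persons": round_sig(persons),
                "pct_of_total_raw": pct,
                "pct_of_total": pct_rounded,
            }
        )
    return pd.DataFrame(rows)
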