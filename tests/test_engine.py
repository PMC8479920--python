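"""Life-course engine: CRN coupling, calibration, accounting, survival oracles."""

import numpy as np
import pandas as pd
import pytest

from sodiumsim.engine import (
    IncidenceRates,
    RiskModel,
    SimulationConfig,
    calibrate,
    run_scenario_pair,
)
from sodiumsim.population import (
    CAUSES,
    N_BANDS,
    ExposureDistributionParams,
    MortalityTargets,
    age_band_index,
    generate_population,
)
from sodiumsim.risk import RelativeRiskParams
from sodiumsim.scenarios import CategoryReductions

YEARS = list(range(2013, 2033))


def constant_targets(rates: dict) -> MortalityTargets:
    """Targets with a constant rate per cause across all strata and years."""
    rows = [
        (year, sex, band, cause, rates[cause])
        for year in YEARS
        for sex in (0, 1)
        for band in range(N_BANDS)
        for cause in CAUSES
    ]
    return MortalityTargets(
        pd.DataFrame(rows, columns=["year", "sex", "age_band", "cause", "rate"])
    )


def flat_risk(death_rates: dict, inc_chd=0.0, inc_stroke=0.0) -> RiskModel:
    """Risk model with RR == 1 everywhere and constant base hazards."""
    return RiskModel(
        relative_risk=RelativeRiskParams(
            logrr={c: np.zeros((2, N_BANDS)) for c in CAUSES}
        ),
        incidence=IncidenceRates(
            chd=np.full((2, N_BANDS), inc_chd), stroke=np.full((2, N_BANDS), inc_stroke)
        ),
        base_mortality={c: np.full((2, N_BANDS), death_rates[c]) for c in CAUSES},
    )


def young_exposure() -> ExposureDistributionParams:
    """All weight on ages 30-59 so nobody ages past 79 within the horizon."""
    w = np.array([0.4, 0.35, 0.25, 0.0, 0.0, 0.0])
    return ExposureDistributionParams(age_band_weights=w)


class TestCalibrate:
    def test_factor_is_target_over_expected(self, exposure_params):
        cohort = generate_population(2_000, 2013, exposure_params, seed=1)
        risk = flat_risk({"chd": 0.005, "stroke": 0.005, "other": 0.005})
        targets = constant_targets({"chd": 0.01, "stroke": 0.005, "other": 0.0025})
        factors = calibrate(cohort, targets, risk, years=YEARS)
        assert factors.factor(2020, "chd") == pytest.approx(np.full((2, N_BANDS), 2.0))
        assert factors.factor(2020, "stroke") == pytest.approx(np.ones((2, N_BANDS)))
        assert factors.factor(2020, "other") == pytest.approx(np.full((2, N_BANDS), 0.5))

    def test_zero_expected_with_positive_target_errors(self, exposure_params):
        cohort = generate_population(500, 2013, exposure_params, seed=1)
        risk = flat_risk({"chd": 0.0, "stroke": 0.005, "other": 0.005})
        targets = constant_targets({"chd": 0.01, "stroke": 0.005, "other": 0.005})
        with pytest.raises(ValueError, match="cause=chd"):
            calibrate(cohort, targets, risk, years=YEARS)


class TestDegenerateDynamics:
    def test_zero_hazards_no_events(self):
        cfg = SimulationConfig(cohort_size=1_000, seed=2, entrant_rate=0.0)
        risk = flat_risk({c: 0.0 for c in CAUSES})
        pair = run_scenario_pair(
            cfg, risk=risk, targets=constant_targets({c: 0.0 for c in CAUSES})
        )
        table = pair.baseline.ledger.table
        for col in table.columns:
            if col.startswith(("incident", "deaths")):
                assert table[col].sum() == 0
        assert (pair.baseline.ledger.totals["alive"] == 1_000).all()

    def test_certain_death_empties_cohort_in_first_year(self):
        cfg = SimulationConfig(cohort_size=500, seed=2, entrant_rate=0.0)
        risk = flat_risk({"chd": 0.0, "stroke": 0.0, "other": 1.0})
        pair = run_scenario_pair(
            cfg, risk=risk, targets=constant_targets({"chd": 0.0, "stroke": 0.0, "other": 1.0})
        )
        totals = pair.baseline.ledger.totals
        assert totals.loc[2013, "deaths"] == 500
        assert (totals["alive"] == 0).all()

    def test_constant_hazard_survival_matches_closed_form(self):
        # survivors after T years of constant all-cause hazard h: n(1-h)^T
        n, h = 20_000, 0.02
        rates = {"chd": 0.004, "stroke": 0.004, "other": 0.012}
        cfg = SimulationConfig(cohort_size=n, seed=9, entrant_rate=0.0)
        pair = run_scenario_pair(
            cfg,
            exposure=young_exposure(),
            risk=flat_risk(rates),
            targets=constant_targets(rates),
        )
        survivors = pair.baseline.ledger.totals.loc[2032, "alive"]
        p = (1 - h) ** 20
        se = np.sqrt(n * p * (1 - p))
        assert abs(survivors - n * p) < 3 * se

    def test_cumulative_incidence_matches_closed_form(self):
        # no deaths, constant first-event hazard: 20-year risk 1-(1-h)^20
        n = 20_000
        cfg = SimulationConfig(cohort_size=n, seed=11, entrant_rate=0.0)
        risk = flat_risk({c: 0.0 for c in CAUSES}, inc_chd=0.006, inc_stroke=0.004)
        pair = run_scenario_pair(
            cfg,
            exposure=young_exposure(),
            risk=risk,
            targets=constant_targets({c: 0.0 for c in CAUSES}),
        )
        table = pair.baseline.ledger.table
        incident = table["incident_chd"].sum() + table["incident_stroke"].sum()
        p = 1 - (1 - 0.01) ** 20
        se = np.sqrt(n * p * (1 - p))
        assert abs(incident - n * p) < 3 * se


class TestCommonRandomNumbers:
    def test_null_policy_identity(self):
        cfg = SimulationConfig(cohort_size=5_000, seed=5)
        null = CategoryReductions(np.zeros(2), np.array([0.5, 0.5]))
        pair = run_scenario_pair(cfg, reductions=null)
        assert pair.baseline.ledger.equals(pair.policy.ledger)
        pd.testing.assert_frame_equal(pair.baseline.yearly, pair.policy.yearly)

    def test_same_seed_reproduces_both_ledgers(self):
        a = run_scenario_pair(SimulationConfig(cohort_size=4_000, seed=17))
        b = run_scenario_pair(SimulationConfig(cohort_size=4_000, seed=17))
        assert a.baseline.ledger.equals(b.baseline.ledger)
        assert a.policy.ledger.equals(b.policy.ledger)

    def test_policy_death_never_earlier_per_person(self, paired_run):
        b, p = paired_run.baseline, paired_run.policy
        db = np.where(b.death_year < 0, 10**6, b.death_year)
        dp = np.where(p.death_year < 0, 10**6, p.death_year)
        assert np.all(dp >= db)

    def test_policy_incidence_never_earlier_while_coupled(self, paired_run):
        # incidence may only come earlier in the policy arm for a person whose
        # baseline copy had already died (postponement decoupling)
        b, p = paired_run.baseline, paired_run.policy
        ib = np.where(b.incidence_year < 0, 10**6, b.incidence_year)
        ip = np.where(p.incidence_year < 0, 10**6, p.incidence_year)
        db = np.where(b.death_year < 0, 10**6, b.death_year)
        earlier = ip < ib
        assert np.all(db[earlier] <= ip[earlier])

    def test_alive_counts_policy_never_below_baseline(self, paired_run):
        diff = (
            paired_run.policy.ledger.table["alive"]
            - paired_run.baseline.ledger.table["alive"]
        )
        assert (diff >= 0).all()

    def test_cumulative_deaths_policy_never_above_baseline(self, paired_run):
        cb = paired_run.baseline.ledger.totals["deaths"].cumsum()
        cp = paired_run.policy.ledger.totals["deaths"].cumsum()
        assert (cp <= cb).all()


class TestAccountingAndLedger:
    def test_population_accounting_closes_every_year(self, paired_run):
        for result in (paired_run.baseline, paired_run.policy):
            totals = result.ledger.totals
            alive = totals["alive"].to_numpy()
            expected = (
                paired_run.initial_alive
                + totals["entrants"].cumsum().to_numpy()
                - totals["deaths"].cumsum().to_numpy()
            )
            np.testing.assert_array_equal(alive, expected)

    def test_case_years_accumulate_beyond_incident_counts(self, paired_run):
        t = paired_run.baseline.ledger.table
        assert t["case_years_chd"].sum() >= t["incident_chd"].sum()
        assert t["case_years_stroke"].sum() >= t["incident_stroke"].sum()
        assert (t >= 0).all().all()

    def test_entrants_arrive_at_age_thirty(self, paired_run):
        entrants = paired_run.entry_year > 2013
        assert np.all(paired_run.universe.age[entrants] == 30)


class TestCalibrationEndToEnd:
    def test_baseline_deaths_match_targets_in_expectation(self):
        """Realised baseline deaths vs an exact per-person expectation pass."""
        rates = {"chd": 0.003, "stroke": 0.003, "other": 0.010}
        cfg = SimulationConfig(cohort_size=30_000, seed=21, entrant_rate=0.02)
        targets = constant_targets(rates)
        pair = run_scenario_pair(
            cfg, exposure=young_exposure(), risk=flat_risk(rates), targets=targets
        )
        # deterministic expectation: everyone faces the constant hazards
        uni, entry = pair.universe, pair.entry_year
        p_alive = np.zeros(uni.n)
        expected = {c: 0.0 for c in CAUSES}
        h_tot = sum(rates.values())
        for year in YEARS:
            p_alive[entry == year] = 1.0
            present = entry <= year
            age = uni.age + (year - entry)
            in_out = present & (age <= 79)
            for c in CAUSES:
                expected[c] += float(np.sum(p_alive[in_out]) * rates[c])
            p_alive[present] *= 1.0 - h_tot
        table = pair.baseline.ledger.table
        for c in CAUSES:
            realised = table[f"deaths_{c}"].sum()
            se = np.sqrt(expected[c])
            assert abs(realised - expected[c]) < 4 * se, c


class TestPolicyNullWhenTmrelAboveExposure:
    def test_sbp_tmrel_above_all_exposures_kills_the_effect(self):
        cfg = SimulationConfig(cohort_size=4_000, seed=6)
        risk = RiskModel()
        risk.relative_risk.sbp_tmrel = 250.0  # nobody exceeds the clip ceiling
        pair = run_scenario_pair(cfg, risk=risk)
        assert pair.baseline.ledger.equals(pair.policy.ledger)
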