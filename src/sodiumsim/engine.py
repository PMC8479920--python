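"""Annual discrete-time life-course simulation for a scenario pair.

The engine evolves an open cohort of synthetic adults year by year over a
20-year horizon (2013-2032 by default). Each person-year follows a fixed
event order: update exposures (secular source-share substitution, policy
sodium reduction, lagged SBP change) -> compute hazards -> draw first-ever
CVD incidence for well persons -> draw cause-specific death -> age by one
year. Baseline and policy scenarios run on the identical cohort with
identical uniform random draws (common random numbers), so ledger
differences isolate the policy effect; cause-specific death hazards are
calibrated to external mortality targets.

Coupling detail: cause attribution shares one uniform per person-year, with
each cause owning a fixed sub-interval of [0, 1) (CHD [0, .3), stroke
[.3, .6), other [.6, 1) for deaths; CHD [0, .5), stroke [.5, 1) for
incidence). Because a hazard-lowering policy only shrinks each interval,
events under the policy are a subset of baseline events cause by cause,
per realisation. When a hazard exceeds its slot width (degenerate configs
only) the affected persons fall back to stacked intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import (
    CAUSES,
    N_BANDS,
    SEXES,
    STATE_CHD,
    STATE_DEAD_CHD,
    STATE_DEAD_OTHER,
    STATE_DEAD_STROKE,
    STATE_STROKE,
    STATE_WELL,
    Cohort,
    ExposureDistributionParams,
    MortalityRateParams,
    MortalityTargets,
    age_band_index,
    draw_sbp,
    generate_population,
    make_mortality_targets,
)
from .risk import (
    DoseResponseParams,
    LagParams,
    RelativeRiskParams,
    delta_sbp,
    effective_hazard,
    lagged_weight,
    relative_risk,
)
from .scenarios import (
    CategoryReductions,
    ScenarioSpec,
    apply_policy_to_intake,
    baseline_scenario,
    draw_category_reductions,
    project_discretionary_substitution,
    reformulation_scenario,
)

__all__ = [
    "SimulationConfig",
    "IncidenceRates",
    "RiskModel",
    "CalibrationFactors",
    "EventLedger",
    "ScenarioState",
    "ScenarioResult",
    "PairedRun",
    "simulate_year",
    "calibrate",
    "run_scenario_pair",
    "default_risk_model",
]

log = logging.getLogger(__name__)

LEDGER_COLUMNS = [
    "incident_chd",
    "incident_stroke",
    "case_years_chd",
    "case_years_stroke",
    "deaths_chd",
    "deaths_stroke",
    "deaths_other",
    "alive",
    "entrants",
]

# fixed cause sub-intervals of the shared uniform (see module docstring)
DEATH_ANCHORS = {"chd": (0.0, 0.3), "stroke": (0.3, 0.3), "other": (0.6, 0.4)}
INCIDENCE_ANCHORS = {"chd": (0.0, 0.5), "stroke": (0.5, 0.5)}


@dataclass
class SimulationConfig:
    """Horizon, cohort size and seeding for one scenario pair."""

    cohort_size: int = 50_000
    start_year: int = 2013
    end_year: int = 2032
    entrant_rate: float = 0.022  # annual entrants at age 30, fraction of cohort_size
    seed: int = 1
    output_age_min: int = 30
    output_age_max: int = 79

    def __post_init__(self):
        if self.end_year - self.start_year + 1 != 20:
            raise ValueError("simulation horizon must be 20 one-year steps")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.entrant_rate < 0:
            raise ValueError("entrant_rate must be >= 0")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))


@dataclass
class IncidenceRates:
    """First-event CVD incidence rates per person-year, (2 sexes, 6 bands).

    No national incidence register backs the model; these are configured
    inputs at plausible magnitudes, sampled in the probabilistic
    sensitivity analysis.
    """

    chd: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [8.0e-4, 2.5e-3, 6.0e-3, 1.3e-2, 2.6e-2, 4.5e-2],
                [4.0e-4, 1.2e-3, 3.0e-3, 7.0e-3, 1.5e-2, 3.0e-2],
            ]
        )
    )
    stroke: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [6.0e-4, 1.8e-3, 4.5e-3, 1.1e-2, 2.5e-2, 5.0e-2],
                [5.0e-4, 1.5e-3, 3.6e-3, 9.0e-3, 2.1e-2, 4.5e-2],
            ]
        )
    )

    def rate(self, disease: str) -> np.ndarray:
        return np.asarray(getattr(self, disease), dtype=float)

    def validate(self) -> None:
        for d in ("chd", "stroke"):
            r = self.rate(d)
            if r.shape != (2, N_BANDS) or np.any(r < 0) or np.any(r >= 1):
                raise ValueError(f"{d} incidence rates must be (2, 6) in [0, 1)")


@dataclass
class RiskModel:
    """Bundle of all risk machinery the engine consumes."""

    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    relative_risk: RelativeRiskParams = field(default_factory=RelativeRiskParams)
    lag: LagParams = field(default_factory=LagParams)
    incidence: IncidenceRates = field(default_factory=IncidenceRates)
    #: population-average reference death rates per cause, (2, 6); the
    #: calibration factors carry the year-on-year trend relative to these
    base_mortality: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.dose_response.validate()
        self.relative_risk.validate()
        self.incidence.validate()
        for cause in CAUSES:
            if cause in self.base_mortality:
                r = np.asarray(self.base_mortality[cause], dtype=float)
                if r.shape != (2, N_BANDS) or np.any(r < 0) or np.any(r > 1):
                    raise ValueError(f"base_mortality[{cause}] must be (2, 6) in [0, 1]")


def default_risk_model() -> RiskModel:
    return RiskModel()


@dataclass
class CalibrationFactors:
    """Multiplicative hazard adjustments per year x cause x (sex, band)."""

    factors: dict  # cause -> {year: (2, 6) array}

    def factor(self, year: int, cause: str) -> np.ndarray:
        return self.factors[cause][year]

    def summary(self) -> pd.DataFrame:
        rows = []
        for cause, per_year in self.factors.items():
            for year, arr in per_year.items():
                rows.append((cause, year, float(np.min(arr)), float(np.max(arr))))
        return pd.DataFrame(rows, columns=["cause", "year", "min_factor", "max_factor"])


class EventLedger:
    """Per-scenario event counts by year x sex x age band (output ages only).

    ``table`` has a (year, sex, age_band) index and the count columns in
    :data:`LEDGER_COLUMNS`. ``totals`` tracks the whole cohort (all ages,
    including 80+) per year for population-accounting closure:
    alive(t) = alive(t-1) + entrants(t) - deaths(t).
    """

    def __init__(self, years):
        index = pd.MultiIndex.from_product(
            [years, list(SEXES), range(N_BANDS)], names=["year", "sex", "age_band"]
        )
        self.table = pd.DataFrame(0.0, index=index, columns=LEDGER_COLUMNS)
        self.totals = pd.DataFrame(
            0.0, index=pd.Index(years, name="year"), columns=["alive", "deaths", "entrants"]
        )

    def add_year(self, year, stratum_counts: dict, totals: dict) -> None:
        for col, arr in stratum_counts.items():
            for sex in SEXES:
                for band in range(N_BANDS):
                    self.table.loc[(year, sex, band), col] = arr[sex, band]
        for col, val in totals.items():
            self.totals.loc[year, col] = val

    def check_accounting(self, initial_alive: int) -> None:
        """Raise if alive + cumulative deaths - entrants drifts from the start."""
        alive = self.totals["alive"].to_numpy()
        deaths = self.totals["deaths"].to_numpy()
        entrants = self.totals["entrants"].to_numpy()
        expected = initial_alive + np.cumsum(entrants) - np.cumsum(deaths)
        if not np.array_equal(alive, expected):
            raise AssertionError("population accounting does not close")

    def equals(self, other: "EventLedger") -> bool:
        return self.table.equals(other.table) and self.totals.equals(other.totals)

    def frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def _stratum_index(sex, band):
    return sex * N_BANDS + band


def _stratum_mean(values, sex, band, mask):
    """Mean of ``values`` per (sex, band) stratum over ``mask``; 1 where empty."""
    idx = _stratum_index(sex, band)
    sums = np.bincount(idx[mask], weights=values[mask], minlength=2 * N_BANDS)
    counts = np.bincount(idx[mask], minlength=2 * N_BANDS)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 1.0)
    return means.reshape(2, N_BANDS)


def _stratum_count(sex, band, mask):
    idx = _stratum_index(sex, band)
    return np.bincount(idx[mask], minlength=2 * N_BANDS).astype(float).reshape(2, N_BANDS)


def _anchored_events(u, hazards: dict, anchors: dict, eligible):
    """Cause-specific event masks from one shared uniform per person.

    Each cause owns the interval [anchor, anchor + hazard); persons whose
    hazard exceeds the slot width fall back to stacked intervals (order of
    ``anchors``). Returns {cause: bool mask}.
    """
    causes = list(anchors)
    widths = np.array([anchors[c][1] for c in causes])
    fits = np.ones_like(u, dtype=bool)
    for c, w in zip(causes, widths):
        fits &= hazards[c] <= w
    events = {}
    cum = np.zeros_like(u)
    for c in causes:
        lo, _ = anchors[c]
        anchored = (u >= lo) & (u < lo + hazards[c])
        stacked = (u >= cum) & (u < cum + hazards[c])
        cum = cum + hazards[c]
        events[c] = eligible & np.where(fits, anchored, stacked)
    return events


class ScenarioState:
    """Mutable per-scenario simulation state over a fixed person universe.

    All persons (initial cohort plus every future entrant) are materialised
    up front with an ``entry_year``; a person is *present* once the clock
    reaches it. Dead persons stay in place so both scenarios keep identical
    array indexing for common random numbers.
    """

    def __init__(
        self,
        universe: Cohort,
        entry_year: np.ndarray,
        scenario: ScenarioSpec,
        reductions: CategoryReductions | None,
        risk: RiskModel,
        calibration: CalibrationFactors,
        years,
    ):
        self.universe = universe
        self.entry_year = np.asarray(entry_year, dtype=np.int64)
        self.scenario = scenario
        self.reductions = reductions
        self.risk = risk
        self.calibration = calibration
        self.years = list(years)
        n = universe.n
        self.state = np.full(n, STATE_WELL, dtype=np.int64)
        # person-level event times (-1 = never): the policy arm can never
        # see an earlier event than baseline under common random numbers
        self.incidence_year = np.full(n, -1, dtype=np.int64)
        self.death_year = np.full(n, -1, dtype=np.int64)
        self.prev_dsbp = np.zeros(n)
        self.increments = np.zeros((n, len(self.years)))
        self.lag_weights = np.array(
            [lagged_weight(d, risk.lag) for d in range(len(self.years))]
        )
        # filled by the baseline run, reused verbatim by the policy run so
        # both scenarios share RR-normalisation denominators
        self.mean_rr: dict = {}
        self.record_mean_rr = False
        self.yearly_rows = []

    # -- helpers -----------------------------------------------------------
    def present(self, year: int) -> np.ndarray:
        return self.entry_year <= year

    def ages(self, year: int) -> np.ndarray:
        return self.universe.age + (year - self.entry_year)

    @property
    def alive(self) -> np.ndarray:
        return self.state < STATE_DEAD_CHD


def simulate_year(
    state: ScenarioState,
    year: int,
    u_incidence: np.ndarray,
    u_death: np.ndarray,
    output_age_range=(30, 79),
) -> dict:
    """Advance one calendar year; returns the ledger increments.

    Event order within the year: exposures -> hazards -> first-CVD incidence
    (well persons) -> cause-specific death -> age by one year. Incident
    persons who die the same year still contribute that year's case-year.
    """
    uni = state.universe
    k = state.years.index(year)
    present = state.present(year)
    age = state.ages(year)
    band = age_band_index(np.maximum(age, 30))
    sex = uni.sex
    alive = state.alive & present
    out_ages = (age >= output_age_range[0]) & (age <= output_age_range[1])

    # --- exposures -------------------------------------------------------
    shares_t = project_discretionary_substitution(uni, year, state.scenario)
    sodium_t = apply_policy_to_intake(
        _View(uni.sodium_total, shares_t[:, 0]), year, state.scenario, state.reductions
    )
    delta_na = np.asarray(sodium_t) - uni.sodium_total
    dsbp_full = delta_sbp(
        delta_na, age, uni.sbp, state.risk.dose_response, sodium_before=uni.sodium_total
    )
    dsbp_full = np.where(present, dsbp_full, 0.0)
    state.increments[:, k] = dsbp_full - state.prev_dsbp
    state.prev_dsbp = dsbp_full

    w = state.lag_weights[: k + 1][::-1]  # weight for change made j years ago
    lagged_dsbp = state.increments[:, : k + 1] @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        lag_frac = np.where(dsbp_full != 0.0, lagged_dsbp / dsbp_full, 0.0)
    lag_frac = np.clip(lag_frac, 0.0, 1.0)

    # --- relative risks --------------------------------------------------
    rr_cf = {}
    rr_cur = {}
    for outcome in CAUSES:
        rr_cf[outcome] = relative_risk(uni.sbp, age, sex, outcome, state.risk.relative_risk)
        rr_cur[outcome] = relative_risk(
            uni.sbp + dsbp_full, age, sex, outcome, state.risk.relative_risk
        )

    well = alive & (state.state == STATE_WELL)

    # RR-normalisation denominators: recorded on the baseline run over its
    # alive sets, replayed identically on the policy run
    if state.record_mean_rr:
        means = {}
        for d in ("chd", "stroke"):
            means[("inc", d)] = _stratum_mean(rr_cf[d], sex, band, well)
        for c in CAUSES:
            means[("death", c)] = _stratum_mean(rr_cf[c], sex, band, alive)
        state.mean_rr[year] = means
    means = state.mean_rr[year]

    # --- hazards ---------------------------------------------------------
    inc_hazard = {}
    for d in ("chd", "stroke"):
        base = state.risk.incidence.rate(d)[sex, band]
        inc_hazard[d] = np.where(
            well,
            effective_hazard(
                base,
                rr_cur[d],
                rr_cf[d],
                lag_frac,
                1.0,
                mean_rr=means[("inc", d)][sex, band],
                warn_label=f"incidence {d} {year}",
            ),
            0.0,
        )
    death_hazard = {}
    for c in CAUSES:
        base = np.asarray(state.risk.base_mortality[c], dtype=float)[sex, band]
        calib = state.calibration.factor(year, c)[sex, band]
        death_hazard[c] = np.where(
            alive,
            effective_hazard(
                base,
                rr_cur[c],
                rr_cf[c],
                lag_frac,
                calib,
                mean_rr=means[("death", c)][sex, band],
                warn_label=f"death {c} {year}",
            ),
            0.0,
        )

    # --- incidence draws (first CVD event only) --------------------------
    inc_events = _anchored_events(u_incidence, inc_hazard, INCIDENCE_ANCHORS, well)
    state.state[inc_events["chd"]] = STATE_CHD
    state.state[inc_events["stroke"]] = STATE_STROKE
    state.incidence_year[inc_events["chd"] | inc_events["stroke"]] = year

    prevalent_chd = alive & (state.state == STATE_CHD)
    prevalent_stroke = alive & (state.state == STATE_STROKE)

    # --- death draws -----------------------------------------------------
    death_events = _anchored_events(u_death, death_hazard, DEATH_ANCHORS, alive)
    state.state[death_events["chd"]] = STATE_DEAD_CHD
    state.state[death_events["stroke"]] = STATE_DEAD_STROKE
    state.state[death_events["other"]] = STATE_DEAD_OTHER
    any_death = death_events["chd"] | death_events["stroke"] | death_events["other"]
    state.death_year[any_death] = year

    alive_after = state.alive & present
    # the starting cohort is stock, not flow: no entrants in the first year
    if year == state.years[0]:
        entrants = np.zeros_like(present)
    else:
        entrants = present & (state.entry_year == year)

    counts = {
        "incident_chd": _stratum_count(sex, band, inc_events["chd"] & out_ages),
        "incident_stroke": _stratum_count(sex, band, inc_events["stroke"] & out_ages),
        "case_years_chd": _stratum_count(sex, band, prevalent_chd & out_ages),
        "case_years_stroke": _stratum_count(sex, band, prevalent_stroke & out_ages),
        "deaths_chd": _stratum_count(sex, band, death_events["chd"] & out_ages),
        "deaths_stroke": _stratum_count(sex, band, death_events["stroke"] & out_ages),
        "deaths_other": _stratum_count(sex, band, death_events["other"] & out_ages),
        "alive": _stratum_count(sex, band, alive_after & out_ages),
        "entrants": _stratum_count(sex, band, entrants & out_ages),
    }
    total_deaths = sum(int(death_events[c].sum()) for c in CAUSES)
    totals = {
        "alive": int(alive_after.sum()),
        "deaths": total_deaths,
        "entrants": int(entrants.sum()),
    }

    # per-year exposure summary over alive persons in the output age range
    mask = alive_after & out_ages
    state.yearly_rows.append(
        {
            "year": year,
            "median_sodium": float(np.median(np.asarray(sodium_t)[mask])) if mask.any() else np.nan,
            "mean_sodium": float(np.mean(np.asarray(sodium_t)[mask])) if mask.any() else np.nan,
            "median_sbp": float(np.median((uni.sbp + lagged_dsbp)[mask])) if mask.any() else np.nan,
        }
    )
    return {"counts": counts, "totals": totals}


class _View:
    """Minimal person-collection view (sodium + processed share arrays)."""

    def __init__(self, sodium_total, processed_share):
        self.sodium_total = sodium_total
        self.processed_share = processed_share


def calibrate(
    cohort: Cohort, targets: MortalityTargets, risk: RiskModel, years=None
) -> CalibrationFactors:
    """Multiplicative factors aligning expected deaths with targets.

    Expected deaths are computed on expected hazards (not realised draws):
    per stratum the mean individual hazard is base * mean(RR)/mean(RR) =
    base, so the factor is target_rate / base_rate. After application the
    expected per-stratum baseline death rate equals the target exactly,
    conditional on the alive set each year.
    """
    risk.validate()
    if years is None:
        years = sorted(targets.table.year.unique())
    band = cohort.age_band
    factors: dict = {c: {} for c in CAUSES}
    for cause in CAUSES:
        base = np.asarray(risk.base_mortality[cause], dtype=float)
        mean_rr = _stratum_mean(
            relative_risk(cohort.sbp, cohort.age, cohort.sex, cause, risk.relative_risk),
            cohort.sex,
            band,
            np.ones(cohort.n, dtype=bool),
        )
        expected = base * mean_rr / mean_rr  # the normalisation cancels in expectation
        for year in years:
            target = targets.rate_array(year, cause)
            bad = (expected <= 0) & (target > 0)
            if np.any(bad):
                s, b = np.argwhere(bad)[0]
                raise ValueError(
                    f"expected deaths are zero but target positive for "
                    f"cause={cause} sex={s} band={b}"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(expected > 0, target / np.where(expected > 0, expected, 1.0), 1.0)
            if np.any(f <= 0):
                raise ValueError(f"non-positive calibration factor for cause={cause}")
            factors[cause][year] = f
    return CalibrationFactors(factors)


@dataclass
class ScenarioResult:
    """One scenario's ledger plus per-year exposure summaries."""

    scenario: ScenarioSpec
    ledger: EventLedger
    yearly: pd.DataFrame  # year, median_sodium, mean_sodium, median_sbp
    incidence_year: np.ndarray | None = None  # per person, -1 = never
    death_year: np.ndarray | None = None
    final_state: np.ndarray | None = None


@dataclass
class PairedRun:
    baseline: ScenarioResult
    policy: ScenarioResult
    calibration: CalibrationFactors
    reductions: CategoryReductions | None
    config: SimulationConfig
    initial_alive: int
    universe: Cohort | None = None  # shared person universe (incl. entrants)
    entry_year: np.ndarray | None = None
    targets: MortalityTargets | None = None


def _build_universe(config: SimulationConfig, exposure: ExposureDistributionParams):
    """Initial cohort plus every future entrant cohort, materialised up front."""
    root = np.random.SeedSequence(config.seed)
    pop_seed, *entrant_seeds = root.spawn(1 + len(config.years) - 1)
    universe = generate_population(config.cohort_size, config.start_year, exposure, pop_seed)
    entry_year = np.full(universe.n, config.start_year, dtype=np.int64)
    n_entrants = int(round(config.entrant_rate * config.cohort_size))
    next_id = universe.n
    if n_entrants > 0:
        entrant_params = _age30_params(exposure)
        for year, seed in zip(config.years[1:], entrant_seeds):
            draw_seed, sbp_seed = seed.spawn(2)
            newcomers = generate_population(
                n_entrants, year, entrant_params, draw_seed, id_offset=next_id
            )
            newcomers.age[:] = 30  # entrants join at exact age 30
            newcomers.sbp = draw_sbp(
                newcomers.age,
                newcomers.sex,
                newcomers.sodium_total,
                entrant_params,
                np.random.default_rng(sbp_seed),
            )
            next_id += newcomers.n
            universe.extend(newcomers)
            entry_year = np.concatenate(
                [entry_year, np.full(newcomers.n, year, dtype=np.int64)]
            )
    return universe, entry_year


def _age30_params(exposure: ExposureDistributionParams) -> ExposureDistributionParams:
    """Exposure params concentrated on the age-30 stratum (entrant draws)."""
    from dataclasses import replace

    w = np.zeros(N_BANDS)
    w[0] = 1.0
    return replace(exposure, age_band_weights=w, implied_checks=False)


def _uniforms(seed: int, year: int, n: int):
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7, year)))
    return rng.uniform(size=n), rng.uniform(size=n)


def _run_one(
    config: SimulationConfig,
    universe: Cohort,
    entry_year: np.ndarray,
    scenario: ScenarioSpec,
    reductions,
    risk: RiskModel,
    calibration: CalibrationFactors,
    mean_rr: dict | None,
) -> tuple[ScenarioResult, dict]:
    state = ScenarioState(
        universe, entry_year, scenario, reductions, risk, calibration, config.years
    )
    if mean_rr is None:
        state.record_mean_rr = True
    else:
        state.mean_rr = mean_rr
    ledger = EventLedger(config.years)
    for year in config.years:
        u_inc, u_death = _uniforms(config.seed, year, universe.n)
        increments = simulate_year(
            state,
            year,
            u_inc,
            u_death,
            output_age_range=(config.output_age_min, config.output_age_max),
        )
        ledger.add_year(year, increments["counts"], increments["totals"])
    yearly = pd.DataFrame(state.yearly_rows)
    result = ScenarioResult(
        scenario,
        ledger,
        yearly,
        incidence_year=state.incidence_year,
        death_year=state.death_year,
        final_state=state.state.copy(),
    )
    return result, state.mean_rr


def run_scenario_pair(
    config: SimulationConfig,
    exposure: ExposureDistributionParams | None = None,
    risk: RiskModel | None = None,
    targets: MortalityTargets | None = None,
    rate_params: MortalityRateParams | None = None,
    scenario_baseline: ScenarioSpec | None = None,
    scenario_policy: ScenarioSpec | None = None,
    reductions: CategoryReductions | None = None,
) -> PairedRun:
    """Run baseline and reformulation on the same cohort with shared draws.

    Both scenarios consume the identical person universe and identical
    per-year uniform streams; the policy run also reuses the baseline run's
    RR-normalisation denominators, so a null policy reproduces the baseline
    ledger bit for bit and a hazard-lowering policy can only remove events.
    """
    exposure = exposure or ExposureDistributionParams()
    risk = risk or default_risk_model()
    scenario_baseline = scenario_baseline or baseline_scenario()
    scenario_policy = scenario_policy or reformulation_scenario()
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    if targets is None:
        rate_params = rate_params or MortalityRateParams()
        targets = make_mortality_targets(
            rate_params, range(2000, config.end_year + 1), root.spawn(1)[0]
        )
    if not risk.base_mortality:
        risk.base_mortality = {
            c: targets.rate_array(config.start_year, c) for c in CAUSES
        }
    if reductions is None and not scenario_policy.is_baseline:
        red_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
        )
        reductions = draw_category_reductions(0.08, 0.34, 34, red_rng)

    universe, entry_year = _build_universe(config, exposure)
    calibration = calibrate(universe, targets, risk, years=config.years)

    base_result, mean_rr = _run_one(
        config, universe, entry_year, scenario_baseline, None, risk, calibration, None
    )
    policy_result, _ = _run_one(
        config,
        universe,
        entry_year,
        scenario_policy,
        reductions,
        risk,
        calibration,
        mean_rr,
    )
    initial_alive = int(np.sum(entry_year == config.start_year))
    base_result.ledger.check_accounting(initial_alive)
    policy_result.ledger.check_accounting(initial_alive)
    return PairedRun(
        baseline=base_result,
        policy=policy_result,
        calibration=calibration,
        reductions=reductions,
        config=config,
        initial_alive=initial_alive,
        universe=universe,
        entry_year=entry_year,
        targets=targets,
    )
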