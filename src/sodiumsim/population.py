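"""Synthetic adult cohort generation and mortality-calibration targets.

The microsimulation operates on a close-to-reality open cohort of synthetic
adults (ages 30+). Each person carries a daily sodium intake (g/day), the
split of that intake across sources (processed food, discretionary table
salt, other), a systolic blood pressure (SBP, mmHg), and a disease state.
This module draws those traits from configurable conditional distributions
stratified by sex and 10-year age band, builds the demographic projection
table used by the open-cohort entrant schedule, and generates the
cause-specific mortality targets the engine calibrates to.

Conventions
-----------
* sex is coded 0 = male, 1 = female throughout.
* age bands: 30-39, 40-49, 50-59, 60-69, 70-79, 80+ (index 0..5).
* sodium is log-normal within stratum (dietary intake is right-skewed);
  SBP is normal with an age-linear mean, clipped to the physiological
  range [70, 250] mmHg; source shares are Dirichlet with configured means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEX_MALE",
    "SEX_FEMALE",
    "AGE_BAND_LABELS",
    "STATE_WELL",
    "STATE_CHD",
    "STATE_STROKE",
    "STATE_DEAD_CHD",
    "STATE_DEAD_STROKE",
    "STATE_DEAD_OTHER",
    "CAUSES",
    "ConfigurationError",
    "Person",
    "Cohort",
    "ExposureDistributionParams",
    "PopulationStructure",
    "MortalityRateParams",
    "MortalityTargets",
    "age_band_index",
    "generate_population",
    "draw_sbp",
    "make_population_structure",
    "make_mortality_targets",
]

SEX_MALE, SEX_FEMALE = 0, 1
SEXES = (SEX_MALE, SEX_FEMALE)
SEX_LABELS = {SEX_MALE: "male", SEX_FEMALE: "female"}

AGE_BAND_LOWER = np.array([30, 40, 50, 60, 70, 80])
AGE_BAND_LABELS = ["30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
N_BANDS = len(AGE_BAND_LABELS)
MAX_AGE = 89  # single ages 30..89; the top band is open-ended

STATE_WELL = 0
STATE_CHD = 1
STATE_STROKE = 2
STATE_DEAD_CHD = 3
STATE_DEAD_STROKE = 4
STATE_DEAD_OTHER = 5
STATE_LABELS = {
    STATE_WELL: "well",
    STATE_CHD: "chd",
    STATE_STROKE: "stroke",
    STATE_DEAD_CHD: "dead_chd",
    STATE_DEAD_STROKE: "dead_stroke",
    STATE_DEAD_OTHER: "dead_other",
}

CAUSES = ("chd", "stroke", "other")

SBP_MIN, SBP_MAX = 70.0, 250.0


class ConfigurationError(ValueError):
    """Raised when distribution or rate parameters are invalid."""


def age_band_index(age):
    """Map single-year ages to 10-year band indices (30-39 -> 0, ..., 80+ -> 5)."""
    age = np.asarray(age)
    idx = np.clip((age - 30) // 10, 0, N_BANDS - 1)
    return idx.astype(np.int64)


@dataclass
class Person:
    """One synthetic adult; a scalar view used for inspection and testing.

    The simulation itself runs on :class:`Cohort` arrays.
    """

    id: int
    sex: int
    age: int
    sodium_total: float
    source_shares: tuple  # (processed, discretionary, other)
    sbp: float
    state: int = STATE_WELL

    @property
    def processed_share(self) -> float:
        return self.source_shares[0]

    @property
    def discretionary_share(self) -> float:
        return self.source_shares[1]

    @property
    def state_label(self) -> str:
        return STATE_LABELS[self.state]

    def validate(self) -> None:
        if abs(sum(self.source_shares) - 1.0) > 1e-9:
            raise ValueError("source_shares must sum to 1")
        if self.sodium_total <= 0:
            raise ValueError("sodium_total must be positive")
        if not (SBP_MIN <= self.sbp <= SBP_MAX):
            raise ValueError("sbp outside [70, 250] mmHg")
        if self.age < 30:
            raise ValueError("cohort is adults aged 30+")


class Cohort:
    """Struct-of-arrays container for a synthetic population.

    All fields are aligned 1-D numpy arrays; dead persons stay in place
    (their ``state`` marks them) so scenario pairs keep identical indexing.
    """

    def __init__(self, ids, sex, age, sodium_total, shares, sbp, state=None):
        self.id = np.asarray(ids, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.int64)
        self.sodium_total = np.asarray(sodium_total, dtype=np.float64)
        shares = np.asarray(shares, dtype=np.float64)
        if shares.shape != (self.id.size, 3):
            raise ValueError("shares must be (n, 3)")
        self.shares = shares
        self.sbp = np.asarray(sbp, dtype=np.float64)
        self.state = (
            np.zeros(self.id.size, dtype=np.int64)
            if state is None
            else np.asarray(state, dtype=np.int64)
        )

    def __len__(self) -> int:
        return self.id.size

    @property
    def n(self) -> int:
        return self.id.size

    @property
    def processed_share(self):
        return self.shares[:, 0]

    @property
    def discretionary_share(self):
        return self.shares[:, 1]

    @property
    def other_share(self):
        return self.shares[:, 2]

    @property
    def alive(self):
        return self.state < STATE_DEAD_CHD

    @property
    def age_band(self):
        return age_band_index(self.age)

    def person(self, i: int) -> Person:
        return Person(
            id=int(self.id[i]),
            sex=int(self.sex[i]),
            age=int(self.age[i]),
            sodium_total=float(self.sodium_total[i]),
            source_shares=tuple(float(s) for s in self.shares[i]),
            sbp=float(self.sbp[i]),
            state=int(self.state[i]),
        )

    def copy(self) -> "Cohort":
        return Cohort(
            self.id.copy(),
            self.sex.copy(),
            self.age.copy(),
            self.sodium_total.copy(),
            self.shares.copy(),
            self.sbp.copy(),
            self.state.copy(),
        )

    def extend(self, other: "Cohort") -> None:
        """Append another cohort in place (open-cohort entrants)."""
        self.id = np.concatenate([self.id, other.id])
        self.sex = np.concatenate([self.sex, other.sex])
        self.age = np.concatenate([self.age, other.age])
        self.sodium_total = np.concatenate([self.sodium_total, other.sodium_total])
        self.shares = np.vstack([self.shares, other.shares])
        self.sbp = np.concatenate([self.sbp, other.sbp])
        self.state = np.concatenate([self.state, other.state])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "sex": self.sex,
                "age": self.age,
                "sodium_total": self.sodium_total,
                "share_processed": self.processed_share,
                "share_discretionary": self.discretionary_share,
                "share_other": self.other_share,
                "sbp": self.sbp,
                "state": self.state,
            }
        )


@dataclass
class ExposureDistributionParams:
    """Stratum-level exposure distribution parameters.

    ``sodium_mean`` holds the stratum arithmetic mean intake in g/day
    (shape 2 x 6: sex x age band); the log-normal location/scale are derived
    from the mean and a common coefficient of variation. SBP means follow a
    line in age: ``sbp_at_50[sex] + sbp_slope_per_decade * (age - 50) / 10``,
    with a cross-sectional coupling to the person's sodium intake (mmHg per
    g/day of intake above the stratum median).
    """

    sodium_mean: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [4.79, 4.79, 4.70, 4.55, 4.40, 4.25],  # male
                [3.46, 3.46, 3.38, 3.28, 3.18, 3.08],  # female
            ]
        )
    )
    sodium_cv: float = 0.38
    share_means: tuple = (0.35, 0.55, 0.10)  # processed, discretionary, other
    share_concentration: float = 40.0
    sbp_at_50: tuple = (129.8, 124.8)  # male, female; mmHg at age 50
    sbp_sd: tuple = (15.0, 16.0)
    sbp_slope_per_decade: float = 5.0
    sodium_sbp_coupling: float = 1.5  # mmHg per g/day above stratum median
    age_band_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.28, 0.24, 0.20, 0.14, 0.09, 0.05])
    )
    sex_weights: tuple = (0.48, 0.52)
    #: implied-moment plausibility checks apply to full adult mixtures;
    #: single-stratum restrictions (e.g. age-30 entrants) switch them off
    implied_checks: bool = True

    # -- derived -----------------------------------------------------------
    def sodium_sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.sodium_cv**2)))

    def sodium_mu(self) -> np.ndarray:
        """Log-normal location per stratum so the arithmetic mean is honoured."""
        return np.log(np.asarray(self.sodium_mean)) - 0.5 * self.sodium_sigma() ** 2

    def sodium_median(self, sex, band) -> np.ndarray:
        return np.exp(self.sodium_mu()[sex, band])

    def sbp_mean(self, age, sex):
        age = np.asarray(age, dtype=float)
        base = np.asarray(self.sbp_at_50)[sex]
        return base + self.sbp_slope_per_decade * (age - 50.0) / 10.0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        problems = []
        sodium_mean = np.asarray(self.sodium_mean, dtype=float)
        if sodium_mean.shape != (2, N_BANDS):
            problems.append("sodium_mean must be shaped (2 sexes, 6 age bands)")
        elif np.any(sodium_mean <= 0):
            bad = np.argwhere(sodium_mean <= 0)[0]
            problems.append(
                f"sodium_mean must be positive (stratum sex={SEX_LABELS[bad[0]]}, "
                f"band={AGE_BAND_LABELS[bad[1]]})"
            )
        if self.sodium_cv <= 0:
            problems.append("sodium_cv must be > 0")
        if any(s <= 0 for s in self.sbp_sd):
            problems.append("sbp_sd entries must be > 0")
        if self.share_concentration <= 0:
            problems.append("share_concentration must be > 0")
        if abs(sum(self.share_means) - 1.0) > 1e-9:
            problems.append("share_means must sum to 1")
        if any(m <= 0 for m in self.share_means):
            problems.append("share_means must be positive")
        w = np.asarray(self.age_band_weights, dtype=float)
        if w.shape != (N_BANDS,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            problems.append("age_band_weights must be 6 non-negative values summing to 1")
        if not problems and self.implied_checks:
            implied_na = self.implied_sodium_mean()
            if not (3.0 <= implied_na <= 6.0):
                problems.append(
                    f"implied population sodium mean {implied_na:.2f} g/day outside [3, 6]"
                )
            implied_med = self.implied_sbp_median()
            if not (120.0 <= implied_med <= 135.0):
                problems.append(
                    f"implied adult SBP median {implied_med:.1f} mmHg outside [120, 135]"
                )
        if problems:
            raise ConfigurationError("; ".join(problems))

    def implied_sodium_mean(self) -> float:
        w = np.asarray(self.age_band_weights, dtype=float)
        sw = np.asarray(self.sex_weights, dtype=float)
        return float(sw @ np.asarray(self.sodium_mean, dtype=float) @ w)

    def implied_sbp_median(self) -> float:
        """Median of the normal mixture over strata (coupling is median-centred)."""
        from scipy.optimize import brentq
        from scipy.stats import norm

        ages = np.arange(30, MAX_AGE + 1)
        age_w = np.repeat(np.asarray(self.age_band_weights) / 10.0, 10)

        def cdf(x):
            total = 0.0
            for sex in SEXES:
                mu = self.sbp_mean(ages, sex)
                total += self.sex_weights[sex] * np.sum(
                    age_w * norm.cdf(x, mu, self.sbp_sd[sex])
                )
            return total

        return float(brentq(lambda x: cdf(x) - 0.5, SBP_MIN, SBP_MAX))


def draw_sbp(age, sex, sodium_total, params: ExposureDistributionParams, rng):
    """Draw SBP (mmHg) given age, sex and sodium intake.

    The mean is linear in age at the configured per-decade slope, shifted by
    the sodium coupling (centred on the stratum mean intake, which keeps the
    population SBP location at its configured value), and the draw is
    clipped to the physiological range [70, 250].
    """
    age = np.asarray(age)
    sex = np.asarray(sex)
    sodium_total = np.asarray(sodium_total, dtype=float)
    band = age_band_index(age)
    mean = params.sbp_mean(age, sex)
    mean = mean + params.sodium_sbp_coupling * (
        sodium_total - np.asarray(params.sodium_mean, dtype=float)[sex, band]
    )
    sd = np.asarray(params.sbp_sd)[sex]
    draws = rng.normal(mean, sd)
    return np.clip(draws, SBP_MIN, SBP_MAX)


def generate_population(
    n: int, year: int, params: ExposureDistributionParams, seed, id_offset: int = 0
) -> Cohort:
    """Generate ``n`` synthetic adults for calendar ``year``.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the same
    seed and parameters always reproduce the identical cohort. ``year`` is
    carried for provenance only — baseline exposure distributions are treated
    as stationary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)

    sex = rng.choice(2, size=n, p=np.asarray(params.sex_weights))
    band = rng.choice(N_BANDS, size=n, p=np.asarray(params.age_band_weights))
    age = AGE_BAND_LOWER[band] + rng.integers(0, 10, size=n)

    sigma = params.sodium_sigma()
    mu = params.sodium_mu()[sex, band]
    sodium = np.exp(rng.normal(mu, sigma))

    alpha = np.asarray(params.share_means) * params.share_concentration
    shares = rng.dirichlet(alpha, size=n)
    # Dirichlet draws sum to 1 up to float rounding; renormalise exactly.
    shares /= shares.sum(axis=1, keepdims=True)

    sbp = draw_sbp(age, sex, sodium, params, rng)
    ids = id_offset + np.arange(n, dtype=np.int64)
    return Cohort(ids, sex, age, sodium, shares, sbp)


@dataclass
class PopulationStructure:
    """Counts by calendar year x single age x sex, for the open cohort."""

    table: pd.DataFrame  # columns: year, age, sex, count

    def count(self, year: int, age: int, sex: int) -> float:
        t = self.table
        row = t[(t.year == year) & (t.age == age) & (t.sex == sex)]
        return float(row["count"].sum())

    def total(self, year: int) -> float:
        t = self.table
        return float(t.loc[t.year == year, "count"].sum())

    def validate(self) -> None:
        if (self.table["count"] < 0).any():
            raise ConfigurationError("population counts must be non-negative")
        years = sorted(self.table.year.unique())
        totals = np.array([self.total(y) for y in years])
        rel = np.abs(np.diff(totals)) / totals[:-1]
        if np.any(rel >= 0.05):
            warnings.warn("yearly population totals change by >= 5%", stacklevel=2)


def make_population_structure(base_counts, growth_rate: float, years) -> PopulationStructure:
    """Project the adult population forward by ageing, growth and entrants.

    ``base_counts`` is a (n_ages, 2) array of counts for ages 30..89 by sex
    in the first year. Each step ages every cohort by one year while scaling
    it by ``1 + growth_rate`` (net inflow), drops the cohort ageing past 89,
    and admits a new entrant cohort at age 30 that also grows geometrically.
    Zero growth is pure ageing (the year-t+k count at age a+k equals the
    year-t count at age a); on a flat age structure the yearly totals follow
    ``(1 + growth_rate)**k`` exactly. Mortality is deliberately absent: this
    is the demographic bookkeeping table, not the simulation.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    if any(y < 2013 or y > 2032 for y in years):
        raise ValueError("years must lie within 2013-2032")
    if growth_rate <= -1.0:
        raise ValueError("growth_rate must exceed -1")
    base = np.asarray(base_counts, dtype=float)
    n_ages = MAX_AGE - 30 + 1
    if base.shape != (n_ages, 2):
        raise ValueError(f"base_counts must be shaped ({n_ages}, 2)")
    if np.any(base < 0):
        raise ValueError("base_counts must be non-negative")

    entrant0 = base[0].copy()
    rows = []
    counts = base.copy()
    for i, year in enumerate(years):
        if i > 0:
            shifted = np.zeros_like(counts)
            shifted[1:] = counts[:-1] * (1.0 + growth_rate)
            shifted[0] = entrant0 * (1.0 + growth_rate) ** i
            counts = shifted
        for ai in range(n_ages):
            for sex in SEXES:
                rows.append((year, 30 + ai, sex, counts[ai, sex]))
    table = pd.DataFrame(rows, columns=["year", "age", "sex", "count"])
    structure = PopulationStructure(table)
    structure.validate()
    return structure


@dataclass
class MortalityRateParams:
    """Log-linear mortality rate model per stratum x cause.

    ``base_rates[cause]`` is a (2, 6) array of per-person annual death rates
    at the year-2000 level; ``trends[cause]`` the annual additive change on
    the log scale; ``noise_sd`` the log-scale sampling noise applied to the
    observed window only.
    """

    base_rates: dict = field(
        default_factory=lambda: {
            "chd": np.array(
                [
                    [4.0e-4, 1.2e-3, 3.2e-3, 8.0e-3, 2.0e-2, 5.5e-2],
                    [2.0e-4, 6.0e-4, 1.7e-3, 4.6e-3, 1.3e-2, 4.2e-2],
                ]
            ),
            "stroke": np.array(
                [
                    [3.0e-4, 9.0e-4, 2.6e-3, 6.6e-3, 1.7e-2, 5.0e-2],
                    [2.4e-4, 7.2e-4, 2.1e-3, 5.4e-3, 1.5e-2, 4.7e-2],
                ]
            ),
            "other": np.array(
                [
                    [2.4e-3, 4.5e-3, 9.0e-3, 2.0e-2, 4.8e-2, 1.4e-1],
                    [1.4e-3, 2.8e-3, 5.6e-3, 1.3e-2, 3.4e-2, 1.2e-1],
                ]
            ),
        }
    )
    trends: dict = field(
        default_factory=lambda: {"chd": -0.025, "stroke": -0.030, "other": -0.010}
    )
    noise_sd: float = 0.03

    def validate(self, years) -> None:
        problems = []
        for cause in CAUSES:
            rates = np.asarray(self.base_rates[cause], dtype=float)
            if rates.shape != (2, N_BANDS):
                problems.append(f"{cause}: base_rates must be (2, 6)")
                continue
            if np.any(rates <= 0) or np.any(rates >= 1):
                problems.append(f"{cause}: base rates must lie in (0, 1)")
            if np.any(np.diff(rates, axis=1) <= 0):
                problems.append(f"{cause}: base rates must increase with age band")
            horizon = max(years) - 2000
            projected = rates * np.exp(self.trends[cause] * horizon)
            if np.any(projected >= 1):
                problems.append(f"{cause}: trend drives a rate to >= 1 within horizon")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class MortalityTargets:
    """Cause-specific death rates by year x age band x sex.

    ``table`` columns: year, sex, age_band, cause, rate. The observed window
    carries sampling noise; the forecast window extrapolates a per-stratum
    log-linear trend fitted to the observed window. All-cause rates are the
    sum over the three causes by construction.
    """

    table: pd.DataFrame
    observed_end: int = 2016

    def rate(self, year: int, sex: int, band: int, cause: str) -> float:
        t = self.table
        row = t[
            (t.year == year) & (t.sex == sex) & (t.age_band == band) & (t.cause == cause)
        ]
        if row.empty:
            raise KeyError(f"no target for year={year} sex={sex} band={band} cause={cause}")
        return float(row.rate.iloc[0])

    def rate_array(self, year: int, cause: str) -> np.ndarray:
        """(2, 6) array of rates for one year and cause."""
        t = self.table
        sub = t[(t.year == year) & (t.cause == cause)]
        out = np.full((2, N_BANDS), np.nan)
        out[sub.sex.to_numpy(), sub.age_band.to_numpy()] = sub.rate.to_numpy()
        if np.isnan(out).any():
            raise KeyError(f"incomplete targets for year={year} cause={cause}")
        return out

    def all_cause_rate(self, year: int, sex: int, band: int) -> float:
        return sum(self.rate(year, sex, band, c) for c in CAUSES)


def make_mortality_targets(
    rate_params: MortalityRateParams, years, seed
) -> MortalityTargets:
    """Generate observed (2000-2016) and forecast mortality target rates.

    Observed rates follow ``base * exp(trend * (year - 2000) + noise)``;
    forecast years extrapolate an ordinary least-squares log-linear fit to
    the observed window, so with zero noise the forecast is exactly the
    generating trend line (a closed-form oracle for tests).
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be non-empty")
    rate_params.validate(years)
    rng = np.random.default_rng(seed)

    observed_years = np.arange(2000, 2017)
    rows = []
    for cause in CAUSES:
        base = np.asarray(rate_params.base_rates[cause], dtype=float)
        trend = rate_params.trends[cause]
        for sex in SEXES:
            for band in range(N_BANDS):
                noise = rng.normal(0.0, rate_params.noise_sd, size=observed_years.size)
                log_obs = (
                    np.log(base[sex, band]) + trend * (observed_years - 2000) + noise
                )
                # log-linear trend fit on the observed window
                slope, intercept = np.polyfit(observed_years - 2000, log_obs, 1)
                for year in years:
                    if year <= 2016:
                        log_rate = log_obs[year - 2000]
                    else:
                        log_rate = intercept + slope * (year - 2000)
                    rate = float(np.exp(log_rate))
                    if rate >= 1:
                        raise ConfigurationError(
                            f"target rate >= 1 for cause={cause} sex={SEX_LABELS[sex]} "
                            f"band={AGE_BAND_LABELS[band]} year={year}"
                        )
                    rows.append((year, sex, band, cause, rate))
    table = pd.DataFrame(rows, columns=["year", "sex", "age_band", "cause", "rate"])
    return MortalityTargets(table)
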