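"""Structured configuration: schema, validation, defaults and builders.

One YAML file configures the whole pipeline (population, scenario, risk,
costs, PSA blocks). Validation is aggregated — a bad config reports every
violation, not just the first — and missing blocks are filled from the
documented defaults with a logged notice. Builders convert the validated
schema into the runtime parameter objects the engine consumes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .engine import IncidenceRates, RiskModel, SimulationConfig
from .outcomes import CostParams
from .population import (
    ExposureDistributionParams,
    MortalityRateParams,
)
from .risk import DoseResponseParams, LagParams, RelativeRiskParams, build_logrr_table
from .scenarios import (
    DEFAULT_TARGETED_COVERAGE,
    ScenarioSpec,
    baseline_scenario,
    reformulation_scenario,
)

__all__ = [
    "RunConfig",
    "validate_config",
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
    "build_exposure_params",
    "build_risk_model",
    "build_rate_params",
    "build_cost_params",
    "build_sim_config",
    "build_scenarios",
]

log = logging.getLogger(__name__)

_D = ExposureDistributionParams()
_M = MortalityRateParams()
_I = IncidenceRates()


class MortalityBlock(BaseModel):
    base_rates: dict[str, list[list[float]]] = Field(
        default_factory=lambda: {c: np.asarray(_M.base_rates[c]).tolist() for c in _M.base_rates}
    )
    trends: dict[str, float] = Field(default_factory=lambda: dict(_M.trends))
    noise_sd: float = Field(default=_M.noise_sd, ge=0)


class PopulationBlock(BaseModel):
    n: int = Field(default=50_000, ge=1)
    sodium_mean: list[list[float]] = Field(
        default_factory=lambda: np.asarray(_D.sodium_mean).tolist()
    )
    sodium_cv: float = Field(default=_D.sodium_cv, gt=0)
    share_means: list[float] = Field(default_factory=lambda: list(_D.share_means))
    share_concentration: float = Field(default=_D.share_concentration, gt=0)
    sbp_at_50: list[float] = Field(default_factory=lambda: list(_D.sbp_at_50))
    sbp_sd: list[float] = Field(default_factory=lambda: list(_D.sbp_sd))
    sbp_slope_per_decade: float = _D.sbp_slope_per_decade
    sodium_sbp_coupling: float = _D.sodium_sbp_coupling
    age_band_weights: list[float] = Field(
        default_factory=lambda: np.asarray(_D.age_band_weights).tolist()
    )
    sex_weights: list[float] = Field(default_factory=lambda: list(_D.sex_weights))
    growth_rate: float = Field(default=0.01, gt=-1.0)
    entrant_rate: float = Field(default=0.022, ge=0)
    mortality: MortalityBlock = Field(default_factory=MortalityBlock)

    @field_validator("share_means")
    @classmethod
    def _shares_sum(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("share_means must sum to 1")
        return v


class ScenarioBlock(BaseModel):
    ramp_start: int = 2013
    ramp_end: int = 2017
    market_share: float = Field(default=0.70, ge=0.0, le=1.0)
    substitution_rate: float = 0.0
    reduction_range: list[float] = Field(default_factory=lambda: [0.08, 0.34])
    n_categories: int = Field(default=34, ge=1)
    targeted_coverage: float = Field(default=DEFAULT_TARGETED_COVERAGE, gt=0.0, le=1.0)

    @field_validator("reduction_range")
    @classmethod
    def _range_ok(cls, v):
        if len(v) != 2 or not (0 <= v[0] <= v[1] <= 1):
            raise ValueError("reduction_range must be [lo, hi] with 0 <= lo <= hi <= 1")
        return v


class DoseResponseBlock(BaseModel):
    slope: float = Field(default=1.63, gt=0)
    age_modifier: float = 0.45
    htn_modifier: float = 0.80
    sodium_tmrel_g: float = Field(default=1.5, ge=0.614, le=2.391)


class RelativeRiskBlock(BaseModel):
    rr_per_10mmhg: dict[str, float] = Field(
        default_factory=lambda: {"chd": 1.45, "stroke": 1.60, "other": 1.15}
    )
    age_attenuation: float = Field(default=0.80, gt=0, le=1.0)
    sbp_tmrel: float = Field(default=110.0, ge=70, le=250)

    @field_validator("rr_per_10mmhg")
    @classmethod
    def _rr_ge_1(cls, v):
        bad = [k for k, rr in v.items() if rr < 1.0]
        if bad:
            raise ValueError(f"relative risks must be >= 1: {bad}")
        return v


class LagBlock(BaseModel):
    median_years: float = Field(default=5.0, gt=0)
    shape: float = Field(default=2.0, gt=0)


class IncidenceBlock(BaseModel):
    chd: list[list[float]] = Field(default_factory=lambda: np.asarray(_I.chd).tolist())
    stroke: list[list[float]] = Field(
        default_factory=lambda: np.asarray(_I.stroke).tolist()
    )


class RiskBlock(BaseModel):
    dose_response: DoseResponseBlock = Field(default_factory=DoseResponseBlock)
    relative_risk: RelativeRiskBlock = Field(default_factory=RelativeRiskBlock)
    lag: LagBlock = Field(default_factory=LagBlock)
    incidence: IncidenceBlock = Field(default_factory=IncidenceBlock)


class CostsBlock(BaseModel):
    hospitalisation: dict[str, float] = Field(
        default_factory=lambda: {"chd": 1100.0, "stroke": 1350.0}
    )
    ambulatory: dict[str, float] = Field(
        default_factory=lambda: {"chd": 1450.0, "stroke": 1100.0}
    )
    informal: dict[str, float] = Field(
        default_factory=lambda: {"chd": 820.0, "stroke": 1250.0}
    )
    discount_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    discount_base_year: int = 2013
    brl_per_usd: float = Field(default=3.876, gt=0)


class PsaBlock(BaseModel):
    n_iterations: int = Field(default=200, ge=1)


class HorizonBlock(BaseModel):
    start_year: int = 2013
    end_year: int = 2032


class RunConfig(BaseModel):
    """Validated top-level configuration for a full model run."""

    population: PopulationBlock = Field(default_factory=PopulationBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    risk: RiskBlock = Field(default_factory=RiskBlock)
    costs: CostsBlock = Field(default_factory=CostsBlock)
    psa: PsaBlock = Field(default_factory=PsaBlock)
    horizon: HorizonBlock = Field(default_factory=HorizonBlock)
    seed: int = 1
    output_dir: str = "outputs"


def validate_config(raw) -> RunConfig:
    """Validate a raw mapping (or YAML path) into a :class:`RunConfig`.

    Every violation is reported (pydantic aggregates them); missing blocks
    are filled from the documented defaults with a logged notice. Runtime
    parameter invariants (implied population moments, RR monotonicity, ...)
    are checked too, so a config that validates here will run.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TypeError("config must be a mapping or a path to a YAML file")
    for block in ("population", "scenario", "risk", "costs", "psa", "horizon"):
        if block not in raw:
            log.info("config block '%s' missing; using documented defaults", block)
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as err:
        messages = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid configuration: {messages}") from err
    # runtime invariants beyond the schema
    build_exposure_params(cfg).validate()
    build_risk_model(cfg).validate()
    build_rate_params(cfg).validate(range(2000, cfg.horizon.end_year + 1))
    build_cost_params(cfg).validate()
    build_sim_config(cfg)
    return cfg


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    return validate_config(path)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical config dump (run provenance)."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# builders: schema -> runtime parameter objects


def build_exposure_params(cfg: RunConfig) -> ExposureDistributionParams:
    p = cfg.population
    return ExposureDistributionParams(
        sodium_mean=np.asarray(p.sodium_mean, dtype=float),
        sodium_cv=p.sodium_cv,
        share_means=tuple(p.share_means),
        share_concentration=p.share_concentration,
        sbp_at_50=tuple(p.sbp_at_50),
        sbp_sd=tuple(p.sbp_sd),
        sbp_slope_per_decade=p.sbp_slope_per_decade,
        sodium_sbp_coupling=p.sodium_sbp_coupling,
        age_band_weights=np.asarray(p.age_band_weights, dtype=float),
        sex_weights=tuple(p.sex_weights),
    )


def build_rate_params(cfg: RunConfig) -> MortalityRateParams:
    m = cfg.population.mortality
    return MortalityRateParams(
        base_rates={c: np.asarray(v, dtype=float) for c, v in m.base_rates.items()},
        trends=dict(m.trends),
        noise_sd=m.noise_sd,
    )


def build_risk_model(cfg: RunConfig) -> RiskModel:
    r = cfg.risk
    logrr = {
        outcome: build_logrr_table(rr, r.relative_risk.age_attenuation)
        for outcome, rr in r.relative_risk.rr_per_10mmhg.items()
    }
    return RiskModel(
        dose_response=DoseResponseParams(
            slope=r.dose_response.slope,
            age_modifier=r.dose_response.age_modifier,
            htn_modifier=r.dose_response.htn_modifier,
            sodium_tmrel_g=r.dose_response.sodium_tmrel_g,
        ),
        relative_risk=RelativeRiskParams(logrr=logrr, sbp_tmrel=r.relative_risk.sbp_tmrel),
        lag=LagParams(median_years=r.lag.median_years, shape=r.lag.shape),
        incidence=IncidenceRates(
            chd=np.asarray(r.incidence.chd, dtype=float),
            stroke=np.asarray(r.incidence.stroke, dtype=float),
        ),
    )


def build_cost_params(cfg: RunConfig) -> CostParams:
    c = cfg.costs
    return CostParams(
        hospitalisation=dict(c.hospitalisation),
        ambulatory=dict(c.ambulatory),
        informal=dict(c.informal),
        discount_rate=c.discount_rate,
        discount_base_year=c.discount_base_year,
        brl_per_usd=c.brl_per_usd,
    )


def build_sim_config(cfg: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        cohort_size=cfg.population.n,
        start_year=cfg.horizon.start_year,
        end_year=cfg.horizon.end_year,
        entrant_rate=cfg.population.entrant_rate,
        seed=cfg.seed,
    )


def build_scenarios(cfg: RunConfig) -> tuple[ScenarioSpec, ScenarioSpec]:
    s = cfg.scenario
    common = dict(
        ramp_start=s.ramp_start,
        ramp_end=s.ramp_end,
        market_share=s.market_share,
        substitution_rate=s.substitution_rate,
    )
    return baseline_scenario(**common), reformulation_scenario(**common)
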