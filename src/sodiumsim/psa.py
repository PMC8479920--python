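"""Second-order Monte Carlo probabilistic sensitivity analysis.

An outer loop samples one complete parameter set per iteration from
configured priors (sampling error of baseline sodium and SBP distributions,
log relative risks, both TMRELs, the dose-response slope, the lag median,
CVD incidence levels, and mortality trends); the inner simulation then runs
a full common-random-numbers scenario pair, jointly propagating parameter
and individual-level stochastic uncertainty. Output cells are summarised by
their empirical median and 2.5/97.5 percentile uncertainty interval
(linear-interpolation quantile definition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import RiskModel, SimulationConfig, run_scenario_pair
from .outcomes import (
    CostParams,
    cost_savings,
    prevented_or_postponed,
    render_cost_results,
    render_results,
)
from .population import ConfigurationError, ExposureDistributionParams, MortalityRateParams
from .risk import LagParams
from .scenarios import draw_category_reductions

__all__ = [
    "Prior",
    "ParameterPriors",
    "PsaDraw",
    "sample_parameters",
    "run_psa",
    "summarise",
]

log = logging.getLogger(__name__)

MAX_RESAMPLE = 100


@dataclass
class Prior:
    """One univariate prior: 'point', 'normal', 'uniform' or 'lognormal'.

    ``params``: point -> (value,); normal -> (mean, sd); uniform ->
    (lo, hi); lognormal -> (log-mean, log-sd). ``bounds`` trigger
    resampling outside them.
    """

    dist: str
    params: tuple
    bounds: tuple | None = None

    def __post_init__(self):
        if self.dist not in ("point", "normal", "uniform", "lognormal"):
            raise ValueError(f"unknown prior family '{self.dist}'")
        if self.dist == "point" and len(self.params) != 1:
            raise ValueError("point prior takes one value")
        if self.dist in ("normal", "uniform", "lognormal") and len(self.params) != 2:
            raise ValueError(f"{self.dist} prior takes two parameters")
        if self.dist == "uniform" and self.params[0] > self.params[1]:
            raise ValueError("uniform prior requires lo <= hi")
        if self.dist in ("normal", "lognormal") and self.params[1] < 0:
            raise ValueError("prior sd must be >= 0")

    def sample(self, rng) -> float:
        for _ in range(MAX_RESAMPLE):
            if self.dist == "point":
                value = self.params[0]
            elif self.dist == "normal":
                value = rng.normal(*self.params)
            elif self.dist == "uniform":
                value = rng.uniform(*self.params)
            else:
                value = float(np.exp(rng.normal(*self.params)))
            if self.bounds is None:
                return float(value)
            lo, hi = self.bounds
            if (lo is None or value >= lo) and (hi is None or value <= hi):
                return float(value)
        raise RuntimeError("prior resampling exceeded 100 attempts")

    @classmethod
    def point(cls, value: float) -> "Prior":
        return cls("point", (value,))


def _default_priors() -> dict:
    return {
        "sodium_mean_scale": Prior("normal", (1.0, 0.02), bounds=(0.8, 1.2)),
        "sbp_mean_shift": Prior("normal", (0.0, 0.3), bounds=(-3.0, 3.0)),
        "dr_slope": Prior("normal", (1.63, 0.20), bounds=(0.05, None)),
        "sodium_tmrel": Prior("uniform", (0.614, 2.391)),
        "sbp_tmrel": Prior("uniform", (105.0, 115.0)),
        "logrr_scale_chd": Prior("normal", (1.0, 0.10), bounds=(0.0, None)),
        "logrr_scale_stroke": Prior("normal", (1.0, 0.10), bounds=(0.0, None)),
        "logrr_scale_other": Prior("normal", (1.0, 0.15), bounds=(0.0, None)),
        "lag_median": Prior("normal", (5.0, 1.0), bounds=(1.0, 15.0)),
        "incidence_scale_chd": Prior("lognormal", (0.0, 0.2)),
        "incidence_scale_stroke": Prior("lognormal", (0.0, 0.2)),
        "mortality_trend_shift": Prior("normal", (0.0, 0.004)),
    }


@dataclass
class ParameterPriors:
    """Priors for every uncertain model parameter, keyed by name."""

    priors: dict = field(default_factory=_default_priors)

    def degenerate(self) -> "ParameterPriors":
        """Collapse every prior to its central value (point masses)."""
        centres = {}
        for name, p in self.priors.items():
            if p.dist == "point":
                c = p.params[0]
            elif p.dist == "uniform":
                c = 0.5 * (p.params[0] + p.params[1])
            elif p.dist == "lognormal":
                c = float(np.exp(p.params[0]))
            else:
                c = p.params[0]
            centres[name] = Prior.point(c)
        return ParameterPriors(centres)


@dataclass
class PsaDraw:
    """One complete sampled parameter set."""

    values: dict
    iteration: int

    def __getitem__(self, key):
        return self.values[key]


def sample_parameters(
    priors: ParameterPriors, iteration_index: int, root_seed: int
) -> PsaDraw:
    """Sample one parameter set, reproducible in (root_seed, iteration)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=root_seed, spawn_key=(40, iteration_index))
    )
    values = {name: prior.sample(rng) for name, prior in priors.priors.items()}
    return PsaDraw(values=values, iteration=iteration_index)


def apply_draw(
    draw: PsaDraw,
    exposure: ExposureDistributionParams,
    risk: RiskModel,
    rate_params: MortalityRateParams,
):
    """Apply a sampled parameter set to base model objects (pure)."""
    v = draw.values
    exposure2 = replace(
        exposure,
        sodium_mean=np.asarray(exposure.sodium_mean) * v["sodium_mean_scale"],
        sbp_at_50=tuple(b + v["sbp_mean_shift"] for b in exposure.sbp_at_50),
    )
    exposure2.validate()

    dr = replace(
        risk.dose_response, slope=v["dr_slope"], sodium_tmrel_g=v["sodium_tmrel"]
    )
    dr.validate()
    logrr = {
        out: np.asarray(risk.relative_risk.logrr[out]) * v[f"logrr_scale_{out}"]
        for out in risk.relative_risk.logrr
    }
    rr = replace(risk.relative_risk, logrr=logrr, sbp_tmrel=v["sbp_tmrel"])
    rr.validate()
    lag = LagParams(
        median_years=v["lag_median"], shape=risk.lag.shape, family=risk.lag.family
    )
    incidence = replace(
        risk.incidence,
        chd=np.asarray(risk.incidence.chd) * v["incidence_scale_chd"],
        stroke=np.asarray(risk.incidence.stroke) * v["incidence_scale_stroke"],
    )
    incidence.validate()
    risk2 = RiskModel(
        dose_response=dr,
        relative_risk=rr,
        lag=lag,
        incidence=incidence,
        base_mortality={},  # refilled from this iteration's targets
    )
    rates2 = replace(
        rate_params,
        trends={
            c: t + v["mortality_trend_shift"] for c, t in rate_params.trends.items()
        },
    )
    return exposure2, risk2, rates2


def _inner_seed(root_seed: int, draw: PsaDraw) -> int:
    """Inner-simulation seed derived from the sampled parameter values.

    Keying the first-order (cohort) randomness to the parameter draw rather
    than the iteration index makes degenerate priors collapse the whole PSA
    to one deterministic run (zero-width intervals) while distinct draws
    still propagate fresh cohort noise.
    """
    bits = [int(np.float64(draw.values[k]).view(np.uint64)) for k in sorted(draw.values)]
    ss = np.random.SeedSequence(entropy=[root_seed, 41] + bits)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _iteration_cells(pair, costs: CostParams) -> list[dict]:
    case_diff = prevented_or_postponed(pair.baseline.ledger, pair.policy.ledger, "cases")
    death_diff = prevented_or_postponed(pair.baseline.ledger, pair.policy.ledger, "deaths")
    health = render_results(case_diff, death_diff)
    savings = cost_savings(case_diff, costs)
    cost_table = render_cost_results(savings)
    rows = []
    for _, r in health.iterrows():
        for col, sex in (("men_raw", "men"), ("women_raw", "women"), ("persons_raw", "persons")):
            rows.append({"cell": f"{r.key}_{sex}", "value": float(r[col])})
    for _, r in cost_table.iterrows():
        for col, sex in (("men_raw", "men"), ("women_raw", "women"), ("persons_raw", "persons")):
            rows.append({"cell": f"cost_{r.key}_{sex}_usd_m", "value": float(r[col])})
    final = pair.policy.yearly.iloc[-1]
    rows.append({"cell": "median_sodium_final_policy", "value": float(final.median_sodium)})
    rows.append({"cell": "median_sbp_final_policy", "value": float(final.median_sbp)})
    return rows


def run_psa(
    config: SimulationConfig,
    n_iterations: int,
    priors: ParameterPriors | None = None,
    exposure: ExposureDistributionParams | None = None,
    risk: RiskModel | None = None,
    rate_params: MortalityRateParams | None = None,
    costs: CostParams | None = None,
    reduction_range: tuple = (0.08, 0.34),
    n_categories: int = 34,
) -> pd.DataFrame:
    """Run the PSA; returns one row per iteration x output cell.

    Iterations are independent and keyed by (config.seed, index), so the
    result is order-invariant and parallelisable by iteration. A failing
    iteration is recorded (cell 'failed') and the run continues.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    priors = priors or ParameterPriors()
    exposure = exposure or ExposureDistributionParams()
    risk = risk or RiskModel()
    rate_params = rate_params or MortalityRateParams()
    costs = costs or CostParams()

    all_rows = []
    failures = 0
    for i in range(n_iterations):
        try:
            for attempt in range(MAX_RESAMPLE):
                draw = sample_parameters(priors, i + attempt * 10_000, config.seed)
                draw.iteration = i
                try:
                    exposure_i, risk_i, rates_i = apply_draw(
                        draw, exposure, risk, rate_params
                    )
                    break
                except (ConfigurationError, ValueError):
                    log.warning("iteration %d: sampled set invalid, resampling", i)
            else:
                raise RuntimeError("parameter resampling exceeded 100 attempts")
            inner = _inner_seed(config.seed, draw)
            config_i = replace(config, seed=inner)
            red_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=inner, spawn_key=(42,))
            )
            reductions = draw_category_reductions(
                reduction_range[0], reduction_range[1], n_categories, red_rng
            )
            pair = run_scenario_pair(
                config_i,
                exposure=exposure_i,
                risk=risk_i,
                rate_params=rates_i,
                reductions=reductions,
            )
            for row in _iteration_cells(pair, costs):
                row["iteration"] = i
                all_rows.append(row)
        except Exception:  # noqa: BLE001 - a single iteration must not kill the run
            failures += 1
            log.exception("PSA iteration %d failed", i)
            all_rows.append({"cell": "failed", "value": 1.0, "iteration": i})
    if failures:
        log.warning("PSA completed with %d failed iterations", failures)
    return pd.DataFrame(all_rows, columns=["iteration", "cell", "value"])


def summarise(iteration_table: pd.DataFrame) -> pd.DataFrame:
    """Median and 95% uncertainty interval per output cell.

    Empirical 2.5th/50th/97.5th percentiles with the linear-interpolation
    quantile definition; one row per cell with the iteration count.
    """
    if iteration_table.empty:
        raise ValueError("iteration table is empty")
    rows = []
    for cell, group in iteration_table.groupby("cell"):
        vals = group["value"].to_numpy(dtype=float)
        lo, med, hi = np.percentile(vals, [2.5, 50.0, 97.5], method="linear")
        rows.append(
            {
                "cell": cell,
                "median": float(med),
                "p2_5": float(lo),
                "p97_5": float(hi),
                "n_iterations": int(vals.size),
            }
        )
    out = pd.DataFrame(rows)
    assert ((out.p2_5 <= out["median"]) & (out["median"] <= out.p97_5)).all()
    return out


def format_interval(median: float, lo: float, hi: float, digits: int = 2) -> str:
    """Render a PSA cell like the published tables: 'x (lo to hi)'."""
    from .outcomes import round_sig

    def fmt(v):
        r = round_sig(v, digits)
        return f"{r:g}"

    return f"{fmt(median)} ({fmt(lo)} to {fmt(hi)})"
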