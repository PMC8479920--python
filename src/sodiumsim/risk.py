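"""Sodium -> SBP -> disease risk machinery.

Three pieces: a linear dose-response converting a sodium change (g/day) into
an SBP change (mmHg), with effect modification by age and hypertensive
status and a theoretical-minimum-risk sodium level (TMREL) below which no
further benefit accrues; log-linear relative risks per 10 mmHg of SBP above
an SBP TMREL (default 110 mmHg), attenuating with age; and a discretised
gamma lag giving the cumulative fraction of a risk change realised a given
number of years after the SBP change (median 5 years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .population import AGE_BAND_LABELS, CAUSES, N_BANDS, age_band_index

__all__ = [
    "DoseResponseParams",
    "RelativeRiskParams",
    "LagParams",
    "delta_sbp",
    "relative_risk",
    "lagged_weight",
    "effective_hazard",
    "build_logrr_table",
]

log = logging.getLogger(__name__)

AGE_BAND_MID = np.array([34.5, 44.5, 54.5, 64.5, 74.5, 84.5])


@dataclass
class DoseResponseParams:
    """Linear sodium -> SBP dose-response with effect modification.

    mmHg change per g/day sodium change =
    ``slope + age_modifier * (age - 50)/10 + htn_modifier * 1[SBP >= 140]``,
    floored at zero so the effect never reverses sign at young ages.
    Intake below ``sodium_tmrel_g`` accrues no further benefit.
    """

    slope: float = 1.63  # mmHg per g/day at age 50, normotensive
    age_modifier: float = 0.45  # extra mmHg per g/day per decade above 50
    htn_modifier: float = 0.80  # extra mmHg per g/day when SBP >= 140
    sodium_tmrel_g: float = 1.5  # g/day; uncertainty range [0.614, 2.391]

    TMREL_RANGE = (0.614, 2.391)

    def validate(self) -> None:
        if self.slope <= 0:
            raise ValueError("dose-response slope must be > 0")
        lo, hi = self.TMREL_RANGE
        if not (lo <= self.sodium_tmrel_g <= hi):
            raise ValueError(
                f"sodium TMREL must lie within [{lo}, {hi}] g/day"
            )


def delta_sbp(
    delta_sodium,
    age,
    current_sbp,
    params: DoseResponseParams,
    sodium_before=None,
):
    """SBP change (mmHg) produced by a sodium change (g/day).

    When ``sodium_before`` is given, only the part of the change above the
    sodium TMREL counts: moving from s0 to s0 + delta contributes
    ``max(s0 + delta, T) - max(s0, T)`` effective grams. The per-gram effect
    is the configured slope plus age and hypertension modifiers (never
    negative). The sign of the result matches the sign of the change.
    """
    delta_sodium = np.asarray(delta_sodium, dtype=float)
    age = np.asarray(age, dtype=float)
    current_sbp = np.asarray(current_sbp, dtype=float)
    if sodium_before is None:
        effective = delta_sodium
    else:
        s0 = np.asarray(sodium_before, dtype=float)
        t = params.sodium_tmrel_g
        effective = np.maximum(s0 + delta_sodium, t) - np.maximum(s0, t)
    per_gram = (
        params.slope
        + params.age_modifier * (age - 50.0) / 10.0
        + params.htn_modifier * (current_sbp >= 140.0)
    )
    per_gram = np.maximum(per_gram, 0.0)
    out = per_gram * effective
    return out if out.ndim else float(out)


def build_logrr_table(rr_at_55: float, attenuation: float = 0.80) -> np.ndarray:
    """(2, 6) log-RR-per-10mmHg table from an RR at ages 50-59.

    The log relative risk attenuates multiplicatively by ``attenuation`` per
    decade of age away from the 50-59 band (the standard pattern for
    SBP-associated risks); sexes share the table unless overridden.
    """
    logrr = np.log(rr_at_55) * attenuation ** ((AGE_BAND_MID - 54.5) / 10.0)
    return np.vstack([logrr, logrr])


@dataclass
class RelativeRiskParams:
    """Log-linear relative risks per 10 mmHg SBP above the SBP TMREL.

    ``logrr[outcome]`` is a (2 sexes, 6 age bands) table of log RRs per
    10 mmHg. RR = 1 at or below ``sbp_tmrel`` (no excess risk), and risk
    rises as exp(logrr * (SBP - TMREL)/10) above it.
    """

    logrr: dict = field(
        default_factory=lambda: {
            "chd": build_logrr_table(1.45),
            "stroke": build_logrr_table(1.60),
            "other": build_logrr_table(1.15),
        }
    )
    sbp_tmrel: float = 110.0

    def validate(self) -> None:
        problems = []
        for outcome in CAUSES:
            if outcome not in self.logrr:
                problems.append(f"missing log-RR table for outcome '{outcome}'")
                continue
            table = np.asarray(self.logrr[outcome], dtype=float)
            if table.shape != (2, N_BANDS):
                problems.append(f"{outcome}: log-RR table must be (2, 6)")
            elif np.any(table < 0):
                problems.append(f"{outcome}: log-RRs must be >= 0")
            elif np.any(np.diff(table, axis=1) > 1e-12):
                problems.append(f"{outcome}: log-RR must not increase with age band")
        if not (70.0 <= self.sbp_tmrel <= 250.0):
            problems.append("sbp_tmrel must be a plausible SBP (70-250 mmHg)")
        if problems:
            raise ValueError("; ".join(problems))


def relative_risk(sbp, age, sex, outcome: str, params: RelativeRiskParams):
    """Relative risk for ``outcome`` at the given SBP, age and sex.

    RR = exp(logRR[sex, band] * max(0, sbp - TMREL) / 10); exactly 1 at or
    below the TMREL and monotone non-decreasing in SBP.
    """
    if outcome not in params.logrr:
        raise KeyError(
            f"unknown outcome '{outcome}'; expected one of {sorted(params.logrr)}"
        )
    sbp = np.asarray(sbp, dtype=float)
    band = age_band_index(age)
    sex_idx = np.asarray(sex, dtype=np.int64)
    logrr = np.asarray(params.logrr[outcome], dtype=float)[sex_idx, band]
    excess = np.maximum(0.0, sbp - params.sbp_tmrel)
    out = np.exp(logrr * excess / 10.0)
    return out if out.ndim else float(out)


@dataclass
class LagParams:
    """Discretised gamma lag between an SBP change and its risk effect.

    The cumulative weight at integer year y is the gamma CDF at y, with the
    scale solved so the CDF hits exactly 0.5 at ``median_years`` (default 5).
    ``shape`` 2 spreads the effect over roughly 1-12 years.
    """

    median_years: float = 5.0
    shape: float = 2.0
    family: str = "gamma"

    def __post_init__(self):
        if self.family != "gamma":
            raise ValueError("only the gamma lag family is implemented")
        if self.median_years <= 0 or self.shape <= 0:
            raise ValueError("lag median and shape must be > 0")
        self._scale = brentq(
            lambda s: gamma_dist.cdf(self.median_years, self.shape, scale=s) - 0.5,
            1e-6,
            100.0 * self.median_years,
        )

    @property
    def scale(self) -> float:
        return self._scale


def lagged_weight(years_since_change, params: LagParams):
    """Cumulative fraction of a risk change realised after ``years``.

    Non-decreasing, 0 at year 0, exactly 0.5 at the configured median,
    tending to 1.
    """
    years = np.asarray(years_since_change, dtype=float)
    if np.any(years < 0):
        raise ValueError("years_since_change must be >= 0")
    out = gamma_dist.cdf(years, params.shape, scale=params.scale)
    return out if out.ndim else float(out)


def effective_hazard(
    base_hazard,
    rr_current,
    rr_counterfactual,
    lag_fraction,
    calibration_factor,
    mean_rr=1.0,
    warn_label: str | None = None,
):
    """Per-year event probability combining calibration, RR and lag.

    hazard = calibration * base * [rr_cf + lag * (rr_cur - rr_cf)] / mean_rr,
    clipped to [0, 1] (clipping is logged). ``mean_rr`` is the stratum
    population-average RR converting marginal (population-average) base
    hazards into individual ones while preserving calibration targets.
    """
    base_hazard = np.asarray(base_hazard, dtype=float)
    rr_current = np.asarray(rr_current, dtype=float)
    rr_counterfactual = np.asarray(rr_counterfactual, dtype=float)
    lagged_rr = rr_counterfactual + np.asarray(lag_fraction) * (
        rr_current - rr_counterfactual
    )
    hazard = (
        np.asarray(calibration_factor) * base_hazard * lagged_rr / np.asarray(mean_rr)
    )
    if np.any(hazard > 1.0) or np.any(hazard < 0.0):
        log.warning(
            "hazard outside [0, 1] clipped%s",
            f" ({warn_label})" if warn_label else "",
        )
    out = np.clip(hazard, 0.0, 1.0)
    return out if out.ndim else float(out)
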