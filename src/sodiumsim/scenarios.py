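"""Policy scenarios: the reformulation ramp and its mapping onto intakes.

The voluntary-reformulation scenario phases in category-level sodium-content
reductions over 2013-2017 (one fifth per year) and sustains them thereafter.
Only the processed-food share of a person's intake is exposed, scaled by the
market share of committed manufacturers (default 0.70); discretionary table
salt and other sources are untouched. The baseline scenario applies no
reduction ever.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScenarioSpec",
    "CategoryReductions",
    "baseline_scenario",
    "reformulation_scenario",
    "reformulation_schedule",
    "draw_category_reductions",
    "apply_policy_to_intake",
    "project_discretionary_substitution",
    "salt_equivalent",
]

#: grams of salt (NaCl) per gram of sodium used for reporting equivalents
SALT_PER_SODIUM = 2.5

#: fraction of processed-food sodium in categories covered by the voluntary
#: targets; with 34 categories reduced uniformly on [0.08, 0.34] this yields
#: an expected full-ramp population intake drop of 0.1 g/day (the realised
#: national effect the model reproduces)
DEFAULT_TARGETED_COVERAGE = 0.486

DEFAULT_REDUCTION_RANGE = (0.08, 0.34)
DEFAULT_N_CATEGORIES = 34


@dataclass
class ScenarioSpec:
    """Definition of one policy scenario.

    ``market_share`` scales every person's achievable reduction (an
    expectation over manufacturers rather than a per-person Bernoulli
    exposure). ``substitution_rate`` is the secular annual shift of intake
    share from discretionary salt to processed food, applied identically in
    both scenarios (default 0: constant source mix counterfactual).
    """

    name: str = "baseline"
    ramp_start: int = 2013
    ramp_end: int = 2017
    market_share: float = 0.70
    substitution_rate: float = 0.0
    post_ramp_behaviour: str = "sustained"

    def __post_init__(self):
        if self.name not in ("baseline", "reformulation"):
            raise ValueError("scenario name must be 'baseline' or 'reformulation'")
        if not (0.0 <= self.market_share <= 1.0):
            raise ValueError("market_share must lie in [0, 1]")
        if self.ramp_start > self.ramp_end:
            raise ValueError("ramp_start must not exceed ramp_end")

    @property
    def is_baseline(self) -> bool:
        return self.name == "baseline"


def baseline_scenario(**kwargs) -> ScenarioSpec:
    return ScenarioSpec(name="baseline", **kwargs)


def reformulation_scenario(**kwargs) -> ScenarioSpec:
    return ScenarioSpec(name="reformulation", **kwargs)


@dataclass
class CategoryReductions:
    """Fractional sodium-content reductions per food category at full ramp.

    ``weights`` are shares of the processed-sodium basket and sum to 1;
    untargeted sodium is carried as a final residual category with zero
    reduction so the basket is complete.
    """

    reductions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.reductions = np.asarray(self.reductions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.reductions.shape != self.weights.shape:
            raise ValueError("reductions and weights must align")
        if np.any((self.reductions < 0) | (self.reductions > 1)):
            raise ValueError("reductions must lie in [0, 1]")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def effective_reduction(self) -> float:
        """Basket-weighted mean fractional reduction of processed sodium."""
        return float(self.weights @ self.reductions)


def reformulation_schedule(spec: ScenarioSpec, year: int) -> float:
    """Fraction of full reformulation achieved by ``year``.

    Zero before the ramp, one at and after its end, linear in equal annual
    steps in between (2013 -> 0.2, ..., 2017 -> 1.0 at defaults). The
    baseline scenario always returns 0.
    """
    if year < 2000:
        raise ValueError("year must be >= 2000")
    if spec.is_baseline:
        return 0.0
    steps = spec.ramp_end - spec.ramp_start + 1
    frac = (year - spec.ramp_start + 1) / steps
    return float(np.clip(frac, 0.0, 1.0))


def draw_category_reductions(
    range_lo: float,
    range_hi: float,
    k_categories: int,
    rng,
    coverage: float = DEFAULT_TARGETED_COVERAGE,
    weights=None,
) -> CategoryReductions:
    """Draw per-category reductions uniform on [range_lo, range_hi].

    Targeted categories share ``coverage`` of the processed-sodium basket
    (equal weights unless ``weights`` gives their relative sizes); the
    remaining ``1 - coverage`` is untargeted sodium with zero reduction.
    """
    if k_categories < 1:
        raise ValueError("k_categories must be >= 1")
    if not (0.0 <= range_lo <= range_hi <= 1.0):
        raise ValueError("require 0 <= range_lo <= range_hi <= 1")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    reductions = rng.uniform(range_lo, range_hi, size=k_categories)
    if weights is None:
        w = np.full(k_categories, coverage / k_categories)
    else:
        w = np.asarray(weights, dtype=float)
        w = coverage * w / w.sum()
    if coverage < 1.0:
        reductions = np.append(reductions, 0.0)
        w = np.append(w, 1.0 - coverage)
    return CategoryReductions(reductions, w)


def apply_policy_to_intake(person, year: int, spec: ScenarioSpec, reductions) -> np.ndarray:
    """New total sodium intake (g/day) after the policy in ``year``.

    ``person`` may be a single :class:`~sodiumsim.population.Person` or a
    whole :class:`~sodiumsim.population.Cohort` (anything exposing
    ``sodium_total`` and ``processed_share``). The reduction is
    ``sodium_total * processed_share * effective_reduction * market_share *
    schedule(year)``; other sources are untouched.
    """
    schedule = reformulation_schedule(spec, year)
    eff = reductions.effective_reduction if reductions is not None else 0.0
    sodium = np.asarray(person.sodium_total, dtype=float)
    processed = np.asarray(person.processed_share, dtype=float)
    reduction = sodium * processed * eff * spec.market_share * schedule
    new = sodium - reduction
    if np.any(new <= 0):
        raise ValueError("policy produced non-positive intake")
    return new if new.ndim else float(new)


def project_discretionary_substitution(
    person, year: int, spec: ScenarioSpec, base_year: int = 2013
):
    """Shift intake shares from discretionary salt to processed food.

    The secular replacement trend moves ``substitution_rate`` of total-intake
    share per year from discretionary salt to processed food, clipped when
    the discretionary share is exhausted (with a warning). Total sodium is
    unchanged. Returns an (n, 3) share array (or length-3 for one person).
    """
    shares = np.atleast_2d(
        np.column_stack(
            [
                np.asarray(person.processed_share, dtype=float),
                np.asarray(person.discretionary_share, dtype=float),
                np.asarray(person.other_share, dtype=float),
            ]
        )
        if hasattr(person, "other_share")
        else np.asarray(person.source_shares, dtype=float)
    )
    delta = spec.substitution_rate * max(0, year - base_year)
    if delta == 0.0:
        out = shares.copy()
    else:
        shift = np.minimum(delta, shares[:, 1])
        if np.any(shift < delta):
            warnings.warn(
                "discretionary share exhausted by substitution trend; clipped at 0",
                stacklevel=2,
            )
        out = shares.copy()
        out[:, 0] += shift
        out[:, 1] -= shift
    return out if out.shape[0] > 1 else out[0]


def salt_equivalent(sodium_g):
    """Convert sodium (g/day) to salt/NaCl equivalent (g/day), factor 2.5."""
    sodium_g = np.asarray(sodium_g, dtype=float)
    if np.any(sodium_g < 0):
        raise ValueError("sodium must be non-negative")
    out = sodium_g * SALT_PER_SODIUM
    return out if out.ndim else float(out)
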