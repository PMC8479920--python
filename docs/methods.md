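# Methods

This note documents the model behind `sodiumsim`: its structure and
assumptions, the parameters that matter and their defaults, what the
synthetic-data generator does and does not emulate, the numerical choices,
and the known limitations.

## Model structure

The simulation is an annual discrete-time, individual-level state-transition
model over a 20-year horizon (2013–2032). The causal chain is

    sodium intake → systolic blood pressure (SBP) → first CVD event /
    cause-specific death,

with SBP the sole mediating risk factor. Persons occupy one of six states
(well, prevalent CHD, prevalent stroke, dead of CHD / stroke / other
cause); transitions are forward-only and only the first cardiovascular
event is modelled, so the results quantify primary prevention only.

Within each simulated year the event order is fixed: update exposures
(secular source-share substitution, policy intake reduction, lagged SBP
change) → compute hazards → draw first-CVD incidence for well persons →
draw cause-specific death for everyone alive → age by one year. A person
who becomes incident and dies in the same year still accrues that year's
case-year (case-years are counted after the incidence draws and before the
death draws). Incident cases remain prevalent until death — chronic, no
remission — accruing one case-year per year, the unit annual treatment
costs attach to.

Persons older than 79 keep simulating (they continue to die and to hold
prevalent disease) but are excluded from output aggregation; reported
tables cover ages 30–79 by sex and 10-year age band.

## Synthetic population

The generator draws each person's traits from conditional distributions
stratified by sex × 10-year age band:

* **Sodium intake** — log-normal within stratum (dietary intake is
  right-skewed), parameterised by the stratum arithmetic mean (defaults
  4.25–4.79 g/day for men, 3.08–3.46 for women, declining with age) and a
  common coefficient of variation (0.38). The implied population mean is
  4.0 g/day — double the 2 g/day guideline.
* **Source shares** — Dirichlet with means 0.35 (processed), 0.55
  (discretionary table salt), 0.10 (other) and concentration 40. Only the
  processed share is reachable by reformulation.
* **SBP** — normal with mean linear in age (5 mmHg per decade; 129.8 mmHg
  for men and 124.8 for women at age 50) plus a cross-sectional coupling
  of 1.5 mmHg per g/day of sodium above the stratum mean, clipped to
  [70, 250] mmHg. The intercepts were solved once so the adult mixture
  median is 127.7 mmHg; the coupling is centred on the stratum *mean*
  because centring on the (lower) log-normal median would shift the SBP
  mixture median up by ~0.4 mmHg. Baseline SBP is held constant over each
  person's life course (period cross-sections stand in for cohort ageing;
  the age gradient is carried by entrants and composition).
* **Age/sex structure** — band weights 0.28/0.24/0.20/0.14/0.09/0.05 from
  ages 30–39 to 80+, sexes 0.48/0.52, a younger-adult-heavy structure of
  the middle-income type. The open cohort admits entrants at exact age 30
  (2.2% of the initial cohort per year at defaults) with traits drawn from
  the youngest stratum.

**Mortality targets** are themselves synthetic: per stratum × cause
(CHD / stroke / other), rates follow `base · exp(trend·(year−2000))` with
log-scale noise (SD 0.03) over an observed 2000–2016 window; the forecast
window (2017–2032) extrapolates an OLS log-linear fit to the observed
window. With zero noise the forecast coincides exactly with the generating
line (the closed-form test oracle); with noise the seam at 2016/2017
carries the fit residual (~3%), i.e. the forecast is continuous with the
observed window in expectation. Cause-specific rates sum to the all-cause
rate by construction, and base rates rise monotonically with age.

What the generator does **not** emulate: survey design and weighting,
measurement error in household-acquisition sodium data, the joint
observation problem of intake and blood pressure being measured on
different surveys (it simply draws both per person with a configurable
coupling), regional and socioeconomic heterogeneity, migration, and
secular trends in any risk factor other than the sodium source mix.
Passing tests therefore demonstrate internal correctness of the machinery
— calibration, coupling, accounting, dose–response arithmetic — not
fidelity to any real population's microdata.

## Policy scenarios

The reformulation scenario phases in category-level sodium-content
reductions linearly in five equal annual steps (2013 → 0.2, …, 2017 → 1.0)
and sustains them afterwards. Reductions for the 34 targeted categories
are uniform on [0.08, 0.34]; the targeted categories cover 48.6% of the
processed-sodium basket (the remainder is an explicit zero-reduction
residual category). That coverage is the one calibrated constant in the
scenario block: it makes the expected full-ramp population intake
reduction equal the realised national-scale effect of 0.1 g/day
(4.0 g/day × 0.35 processed × 0.21 mean reduction × 0.486 coverage × 0.70
market share ≈ 0.100).

Market share (0.70) is applied as a deterministic multiplicative
expectation rather than a per-person Bernoulli exposure: the mean effect
is identical and the variance lower. Category reductions are drawn once
per uncertainty-analysis iteration and shared by all persons — the
uncertainty is category-level, not person-level.

A secular substitution trend (share of intake moving from discretionary
salt to processed food, default 0/year) can be switched on; it applies
identically in both scenarios because it is a trend, not a policy. The
default of zero reproduces the constant-source-mix counterfactual.

Salt equivalents use a fixed factor of 2.5 g NaCl per g sodium (the
reporting convention implied by 0.1 g sodium ↔ 0.25 g salt), not the molar
2.542.

## Risk machinery

* **Dose–response**: ΔSBP per g/day sodium = 1.63 + 0.45·(age−50)/10 +
  0.80·1(SBP ≥ 140) mmHg, floored at zero, applied only to the part of the
  change above the sodium TMREL (1.5 g/day central, range 0.614–2.391).
  The coefficients are treated as data in the config, transcribed from the
  trial meta-regression literature.
* **Relative risks**: log-linear per 10 mmHg above the SBP TMREL
  (110 mmHg). Defaults per 10 mmHg at ages 50–59: CHD 1.45, stroke 1.60,
  other-cause mortality 1.15, identical by sex, with log-RR attenuating by
  a factor 0.80 per decade of age. The non-CVD pathway exists because
  hypertension kills through more than modelled CHD/stroke; setting its RR
  to 1 disables it.
* **Lag**: risk changes phase in with a gamma cumulative weight (shape 2,
  scale solved so the CDF is exactly 0.5 at the 5-year median; the median
  is sampled in the uncertainty analysis). The lag applies to the risk
  *difference* between current and counterfactual RR:
  `hazard = calib · base · [RR_cf + w·(RR_cur − RR_cf)] / mean(RR)`.
* **Marginal-to-individual conversion**: base hazards are
  population-average; individuals get `base · RR_i / mean(RR)` with the
  stratum mean RR computed over the baseline scenario's alive set each
  year and reused verbatim by the policy run. This keeps expected
  stratum-level baseline mortality exactly on target conditional on
  survivors, and gives both scenarios identical denominators, which the
  coupling guarantees below require.
* **Calibration**: factors per year × stratum × cause are target rate over
  expected rate, computed on expected hazards (never on realised draws) —
  deterministic, exact in expectation, and reducible to
  `target(t)/base` because the mean-RR normalisation cancels.

CHD and stroke incidence is not calibrated to any register; incidence
levels are configured inputs at plausible magnitudes and are sampled in
the uncertainty analysis.

## Common random numbers and coupling

Both scenarios consume the same person universe (initial cohort plus all
future entrants, materialised up front so array indices never move) and
the same per-year uniform streams keyed to the root seed. Cause
attribution shares one uniform per person-year with each cause owning a
fixed sub-interval of [0, 1) — CHD [0, .3), stroke [.3, .6), other
[.6, 1) for deaths — so a policy that only shrinks hazards shrinks each
cause's interval in place. Consequences, exact per realisation:

* a null policy reproduces the baseline ledger bit for bit;
* no person dies earlier under the policy, and coincident deaths have the
  same cause;
* alive counts under the policy are never below baseline in any
  stratum-year, and cumulative all-cause deaths never above.

Per-stratum-per-year *event* differences, by contrast, are genuinely
signed: a death the policy postpones leaves that person alive to generate
later-year events in the policy arm only. This is mortality displacement,
not a defect — it is why "prevented **or postponed**" is the right term
and why uncertainty intervals on death differences can cross zero. When a
person-year hazard exceeds its interval width (degenerate configurations
such as certain-death tests), those persons fall back to stacked
intervals, preserving marginal probabilities.

## Outcomes and costs

Differences are accumulated per scenario × year × sex × age band: incident
events, case-years of prevalent disease, deaths by cause, alive counts.
"Cases prevented or postponed" means case-years. Costs per case-year
(BRL, annual): CHD 1100 hospitalisation + 1450 ambulatory/medication + 820
informal care; stroke 1350 + 1100 + 1250. These are synthetic plausible
magnitudes in the configured provenance slots (public-system
hospitalisation tables; EU-extrapolated informal care), not transcriptions
of any fee schedule. Costs are discounted at 3%/year to 2013 (the horizon
start; the discount base is a modelling choice, stated rather than
inherited) and converted at R$3.876 per US$. All internal arithmetic is on
raw values; rounding to 2 significant digits (half away from zero on the
significant-digit scale) is presentation-only, and persons = men + women
holds on raw values before rounding. Percent-of-total denominators are the
baseline scenario's cumulative 2013–2032 totals.

## Uncertainty analysis

The outer loop samples one complete parameter set per iteration: normal
priors for the dose–response slope, log-RR scale factors and baseline
distribution perturbations; uniform priors for both TMRELs over their
stated ranges; log-normal for incidence levels; normal for the lag median
(truncated ≥ 1 year) and for a common mortality-trend shift. Families are
modelling choices — the uncertain quantities are named by the problem, the
distributions are not. The inner run propagates individual-level
stochasticity jointly (no nested loop; cohort size controls first-order
noise). The inner simulation seed derives from the sampled parameter
values, so degenerate (point-mass) priors collapse the whole analysis to
one deterministic run with zero-width intervals. An iteration that fails
is logged and skipped; the run continues. Summaries are empirical medians
with 2.5/97.5 percentile intervals under the linear-interpolation quantile
definition. Default 200 iterations for production; the examples and tests
use 2–12 iterations with cohorts of 1,500–5,000 so everything runs in
seconds.

## Numerical choices and problem sizes

* Simulation state is struct-of-arrays NumPy; dead persons stay in place
  to keep scenario indexing aligned.
* The gamma-lag scale is solved with Brent's method at parameter-object
  construction; the SBP-median implied check solves the mixture CDF the
  same way.
* Hazards are clipped to [0, 1] with a logged warning; share substitution
  clips at zero discretionary share with a warning.
* Rounding uses decimal half-away-from-zero arithmetic to avoid binary
  floating artefacts at the 2-significant-digit scale.
* Test problem sizes: unit tests use 500–30,000-person cohorts; the
  shared acceptance fixture is a 50,000-person pair (~3 s) and the median-
  shift check a 200,000-person cohort (~2 s). The full suite completes in
  well under ten minutes on one CPU.

## Limitations

Only blood-pressure-mediated effects are modelled (no gastric cancer, no
potassium-substitution benefit); no recurrent events or distinct
case-fatality state; no behavioural response (compensatory table-salt
use), price effects, or brand dynamics; no private-sector medical costs,
productivity losses, or QALYs/DALYs; entrants inherit the youngest
stratum's distributions, so cohort effects in intake are not represented;
and because the population, targets and unit costs are synthetic, absolute
output magnitudes are internally consistent rather than nationally
representative — relative and structural conclusions are the intended use.
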