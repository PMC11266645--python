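# Methods

## Overview

The package projects an age-structured, North-Sea-cod-like stock over
2030–2100 under deeply uncertain recruitment and warming, and evaluates
constant-catch and constant-harvest-rate policies by the fraction of
sampled futures in which they fail biological or economic objectives. The
pipeline has four stages: synthetic input generation, stock–recruitment
(SR) fitting, the exploratory projection ensemble, and the RDM analytics
(feature scoring, scenario discovery, risk/trade-off/temporal analysis).

## Stock–recruitment models and parameterisation

Five candidate forms are implemented: environmental Ricker
R = αS·e^(−βS−γE), environmental Beverton–Holt
R = e^(−γE)·αS/(1+βS), their climate-insensitive variants (γ absent), and
a two-parameter hockey stick R = α·min(S, S_break). S is spawning-stock
biomass (tonnes), E the sea-surface-temperature anomaly (°C), R
recruitment at age 1 entering the population the year after spawning.

Free parameters are carried on the log scale so that neither fitting nor
uniform sampling can produce negative α or β. The density-dependence
parameter `dd_log` has a form-specific meaning chosen so both families are
dimensionally sensible at cod-like magnitudes: Beverton–Holt β = e^(dd_log)
(≈ 10⁻⁵ t⁻¹, `dd_log` ≈ −11), Ricker β = e^(−dd_log), i.e. `dd_log` is
the log of the density-dependence SSB scale (≈ 2·10⁵ t, `dd_log` ≈ 12). A
raw Ricker β of e¹² t⁻¹ would annihilate recruitment at any SSB, so the
scale reading is the only usable convention for parameters of that
magnitude.

Fitting maximises the lognormal recruitment likelihood (least squares on
log recruits) with multi-start Nelder–Mead (6 restarts, objective
tolerance 10⁻¹⁰; the hockey-stick objective is non-smooth in the
breakpoint, which plain gradient methods handle poorly). Standard errors
are Gauss–Newton: σ̂·sqrt(diag((JᵀJ)⁻¹)) with a two-point Jacobian of the
log-prediction at the optimum and σ̂² = RSS/(n−k). AIC = 2(k+1) − 2·logL
uses the full lognormal likelihood including the −Σ log R Jacobian term so
values are comparable across forms; deviance explained is 1 − RSS/TSS on
log recruits against the intercept-only null. Uniform sampling bounds are
estimate ± SE per free parameter, the convention of the published bounds
table this design reproduces (Ricker log α ∈ [8.67, 12.02],
dd_log ∈ [11.90, 12.64], γ ∈ [0.64, 0.95]; Beverton–Holt
log α ∈ [9.35, 13.23], dd_log ∈ [−11.96, −10.36], γ ∈ [0.69, 1.01]).

The γ ≥ 0 constraint (warming harms recruitment) is enforced where schemes
are sampled, not inside the parameter container: an unbiased fitter must
be free to return small negative γ estimates when the true sensitivity is
zero, which the calibration tests rely on.

## Population model

Numbers at age N_{t,a} evolve annually. SSB and total biomass are measured
at the start of the year, before fishing. The policy is translated to a
fishing-mortality multiplier F by inverting the Baranov catch equation by
bisection on [0, f_cap] (f_cap = 3 yr⁻¹, relative catch tolerance 10⁻⁶;
the objective is monotone so bisection is exact and robust). A
constant-catch policy targets its level directly; a harvest-rate policy
targets level × start-of-year total biomass (all ages, weight-summed). If
the target exceeds the catch attainable at f_cap, the year is flagged
infeasible and F = f_cap. Survival is N_{t+1,a+1} = N_{t,a}·e^(−F·selₐ−Mₐ)
with the oldest class a plus-group accumulating survivors; recruits enter
at age 1 the following year (ICES cod convention). fbar is the mean of
F·selₐ over reference ages 2–4.

Collapse rule: when SSB falls below 10% of MSY B_trigger the run is
flagged collapsed and fishing is terminated (zero catch) for every
remaining year. Sustainable-year counting treats collapse as terminal:
years from the collapse onward never count as management success even if
the unfished stock later rebuilds above the trigger, because a closed
fishery is a management failure, and because crediting post-collapse
recovery would let a *higher* exploitation level out-score a lower one
through collapse-and-rebuild.

The ensemble runs through a vectorised batch engine (fixed-iteration
bisection across all runs simultaneously; 40,000 runs in ~15 s on one
CPU). The scalar projector and the batch engine implement the same
recursion and are cross-checked against each other and against an
independent straight-line reimplementation in the test suite.

## Economics

Revenue assigns a price (EUR/kg) to each caught fish by its individual
weight through a binned price ladder (defaults 1.2–3.6 EUR/kg, larger fish
dearer). Cost is cost_scale · catch^1.2 — any strictly increasing convex
form matches the qualitative behaviour intended (storage, labour and fuel
grow faster than linearly with landings); the exponent and scale are
config-exposed. Prices are constant in time and profits undiscounted: the
profitability metric compares year-by-year profit to a fixed reference,
not a net present value. The reference is the mean annual profit over a
synthetic 2000–2018 hindcast (lognormal catches around 45 kt, the order of
the fishery's landings in that period), with cost_scale calibrated so the
hindcast mean equals 50 M EUR — the anchor used for the profitability
benchmark.

## Synthetic inputs

The generators define the study conditions:

- **Biology** (seeded): von Bertalanffy weights (asymptote 12–15 kg),
  logistic maturity (a50 ≈ 3) and selectivity (a50 ≈ 2.3), natural
  mortality declining ~1.0 → 0.2 yr⁻¹ with age, and a jittered
  exponentially declining initial age composition — six age classes with
  age 6 a plus-group.
- **History** (40 years, for fitting): SSB follows a bounded geometric
  random walk on [3·10⁴, 3·10⁵] t (reflection keeps the SSB contrast the
  density-dependence parameter needs); SST is a stationary AR(1) anomaly
  (φ = 0.5, sd 0.5 °C); recruitment is the generating SR curve times
  lognormal noise (sd 0.3, typical for SR residuals).
- **SST projections**: piecewise-linear warming from 2000 plus AR(1) noise
  (φ = 0.5, innovation sd 0.3 °C); the moderate pathway reaches +1.5 °C by
  2100, the strong pathway shares its slope to 2060 then steepens to
  +3.5 °C. For a fixed seed both scenarios share the noise stream, so the
  strong scenario dominates after 2060 by construction. Projections are
  mean-bias-corrected against the historical series on the 2000–2018
  overlap.
- E is an anomaly relative to the historical reference mean, in the same
  units for fitting and projection, chosen so the e^(−γE) multiplier is
  O(1); whether the original analysis used absolute SST or an anomaly (and
  recruits vs. thousands) is not derivable from the published numbers, and
  this choice is the single assumption under which the published parameter
  magnitudes are interpretable here.

What the generators do *not* emulate: regime shifts or depensation in
recruitment, observation error in SSB/recruitment (the history is an
assessment-style point series), spatial substock structure, and any
feedback of fishing on weights or maturity. Passing tests therefore show
that the method chain is correct and well-calibrated on a world whose
ground truth is known — not that the real stock behaves like this world.

## Experiment design and analytics

Schemes (one SR parameter draw within bounds plus a climate scenario drawn
uniformly) are sampled per SR form and crossed factorially with a policy
set split evenly between constant catches (uniform on [0.4, 200] kt, a
range bracketing the minimum and axis maximum discussed for this fishery)
and harvest rates (uniform on [0.02%, 30%], covering the region where
sustainability risk saturates). Factorial crossing means every policy
faces the same futures, which is what makes per-scheme dose–response
diagnostics possible. Total runs = forms × schemes × policies (default
2 × 200 × 100 = 40,000).

A projection year is *sustainable* when SSB ≥ MSY B_trigger and
fbar ≤ F_MSY (violation is the strict complement, so success and failure
partition every year). Sustainability risk of a policy bin is the
percentage of its runs with any violating year in the period; the
per-policy level axis is binned (default 25 equal-width bins) because the
sampled levels are continuous. Profitability risk uses the analogous
any-year convention (any year with profit below the reference fails the
run); a period-mean alternative is available behind a config switch.
Periods: mid-century 2030–2049, end-of-century 2050–2099, full horizon.
Risks pool both climate scenarios.

Feature scoring fits `GradientBoostingRegressor` (100 trees, learning rate
0.1, depth 3 — library defaults, pinned for reproducibility) to per-run
sustainable-year counts with predictors (policy level, log α, dd_log, γ,
strong-scenario indicator), reporting normalised impurity importances and
20×20 partial-dependence surfaces for level × log α and level × γ.
Scenario discovery flags runs sustainable over the whole horizon and
characterises them by per-policy-bin success frequencies. The trade-off
analysis highlights the binned level minimising summed risk and the level
whose risk ratio is nearest 1 (minimising |log(s/p)| with both risks
floored at 10⁻¹², so a single zero risk only wins when both are zero).

## Numerical and degenerate-input conventions

Bisection tolerances as above; zero targets short-circuit to F = 0;
all-immature initial distributions raise a no-solution error; empty policy
bins are reported as missing, never silently dropped; duplicate candidate
forms are deduplicated; fits that fail all restarts raise a fit-failure
error carrying per-restart diagnostics. Noiseless histories are fitted to
machine precision (SEs floored at 10⁻¹² to keep them positive). All
randomness flows through seeded `numpy.random.Generator` instances; the
whole pipeline is bit-reproducible for a fixed config.

## Emergent behaviour and known limitations

Two structural properties of this synthetic world are worth stating
plainly, because they shape the ensemble results:

- **Ricker overcompensation breaks strict dose–response monotonicity.**
  The environmental Ricker curve is dome-shaped with its peak at
  SSB = e^(dd_log) (147–307 kt). Under the sampled productivity the
  projected stock routinely exceeds that peak, where *heavier* fishing
  raises recruitment by holding SSB nearer the dome. In a small fraction
  of Ricker × constant-catch schemes (a few percent) a higher catch level
  therefore earns more sustainable years than a lower one, typically by
  delaying collapse. Beverton–Holt strata (monotone recruitment) and all
  harvest-rate strata show perfectly monotone dose–response, and binned
  risk curves are monotone throughout — the non-monotonicity is genuine
  population dynamics, not solver noise.
- **The risky period is mid-century, not end-of-century.** The stock is
  initialised exactly at MSY B_trigger, so in the first projection years
  any sizeable catch pushes fbar above F_MSY (and SSB below the trigger)
  while the stock is still small; under the sampled (high) productivity
  the stock then grows well above the trigger, and late-century warming
  only partially erodes that buffer. Pooled mid-century risks therefore
  exceed end-of-century risks at mid-to-high exploitation, and the
  warming-driven ordering (end ≥ mid) emerges only at low exploitation
  levels. A world in which current productivity is close to replacement —
  which the published bounds alone do not determine — would reverse this.

Other limitations: single stock and single fleet, no observation or
implementation error, no in-period management feedback (the policy is
fixed for 71 years by design), recruitment deviates are carried entirely
by parameter sampling (no year-to-year recruitment noise within a run),
and the economic sub-model is a deliberately minimal stand-in for a full
fleet-economics model.

## Problem sizes used by the tests and the acceptance script

Parameter-recovery and model-selection checks use 500-year histories
(noise sd 0.3) and 50 or 20 replicates; dose–response diagnostics use a
2,000-run ensemble (2 × 40 × 25); the qualitative-structure checks and the
acceptance script run the full 40,000-run design plus 800 dedicated
zero-exploitation runs. These sizes keep the whole suite and the
acceptance script each within a few minutes on one CPU while leaving every
estimate's Monte-Carlo error far below the margins being asserted.
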