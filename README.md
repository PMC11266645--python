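# fishrdm

Robust Decision Making (RDM) for long-term fisheries management under deep
uncertainty, applied to a North-Sea-cod-like age-structured stock.

Classical projections of exploited fish stocks hinge on a stock–recruitment
(SR) relationship that the data rarely pin down: the functional form
(Ricker vs. Beverton–Holt), its parameters, and the strength of the
temperature effect on recruitment are all deeply uncertain, as is the
course of climate change itself. Instead of betting on one parameterisation,
this package stress-tests candidate harvest policies — constant catch
(tonnes per year) and constant harvest rate (fraction of stock biomass) —
across tens of thousands of sampled futures, and asks which policies remain
sustainable and profitable across most of them.

## Model core

Recruitment follows environmentally sensitive SR curves driven by spawning
stock biomass *S* (tonnes) and the sea-surface-temperature anomaly *E*
(°C):

- environmental Beverton–Holt: R = e^(−γE) · αS / (1 + βS)
- environmental Ricker:        R = αS · e^(−βS − γE)

with α the initial slope (recruits per tonne of SSB), β the density
dependence and γ ≥ 0 the temperature sensitivity. SSB-related parameters
are carried on the log scale (`log_alpha`, `dd_log`) so fitting and
sampling can never produce negative values; for the Ricker family
`dd_log` is the log of the density-dependence scale in tonnes
(β = e^(−dd_log)), for the Beverton–Holt family β = e^(dd_log).

The population model is an annual age-structured projection over
2030–2100: policies are translated to a fishing mortality F by inverting
the Baranov catch equation
C = Σₐ Fₐ/Zₐ · Nₐ · (1 − e^(−Zₐ)) · wₐ by bisection, cohorts survive
e^(−F·selₐ − Mₐ) with a plus-group, and the stock is evaluated against the
MSY reference points F_MSY = 0.28 yr⁻¹ and MSY B_trigger = 97,800 t. A
coupled economic model turns catches into profit (weight-specific prices
minus a convex cost of catch). The RDM layer samples SR parameterisations
uniformly within the fitted estimate ± SE bounds, crosses 400 such schemes
(200 per SR form, each with a moderate or strong warming scenario) with
100 sampled policies — 40,000 projections — and then scores uncertainty
importance with gradient-boosted regression trees, discovers the
successful-scenario region, and maps sustainability-vs-profitability risk
trade-offs for mid-century (2030–2049) and end-of-century (2050–2099).

Everything runs from synthetic inputs with known ground truth (generated
by `fishrdm.synthetic_data`), so the full analysis is reproducible and
testable offline; real data in the same CSV layouts can be substituted.

## Worked example

```python
from fishrdm import synthetic_data as sd, sr_models as sr, population_model as pm, rdm_analysis as ra

bio = sd.generate_biology(n_ages=6, seed=1)
params, _ = sr.table1_midpoint_params("env_ricker")
sst = sd.generate_sst_projection("strong", seed=2)
refpts = pm.ReferencePoints()
run = pm.project(bio, params, pm.PolicySpec("harvest_rate", 0.15), sst, refpts)
print(f"SSB 2030: {run.ssb[0]:,.0f} t -> SSB 2100: {run.ssb[-1]:,.0f} t")
print(f"mean catch: {run.catch.mean():,.0f} t/yr, max fbar: {run.fbar.max():.3f}/yr")
print(f"sustainable years: {ra.sustainable_years(run, refpts)} of {len(run.years)}")
```

prints

```
SSB 2030: 97,800 t -> SSB 2100: 288,519 t
mean catch: 152,421 t/yr, max fbar: 0.539/yr
sustainable years: 66 of 71
```

i.e. under this sampled future a 15% harvest rate lets the stock grow well
above the biomass trigger, but fishing mortality exceeds F_MSY in 5 of the
71 years, so the run is not fully successful.

## The full pipeline

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_generate_inputs.py          # synthetic inputs -> results/inputs/
python analysis/02_fit_recruitment_models.py   # SR fits, AIC table, sampling bounds
python analysis/03_run_ensemble.py             # the 40,000-run ensemble (use --quick to downscale)
python analysis/04_rdm_analysis.py             # feature scores, discovery, risks, trade-offs
```

or equivalently through the CLI: `fishrdm all --config configs/default.yaml
--out results`. Each stage writes CSV artifacts plus a provenance record
(config hash, seed, package version).

## Layout

- `src/fishrdm/` — `synthetic_data` (generators + CSV IO), `sr_models`
  (SR curves, fitting, bounds), `population_model` (projector + vectorised
  batch engine), `economics`, `exploratory_modeling` (design + ensemble),
  `rdm_analysis` (feature scoring, discovery, risks), `cli_io` (config,
  stages, CLI).
- `analysis/` — the numbered narrative drivers.
- `configs/default.yaml` — the pinned full-scale configuration.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and known limitations.
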