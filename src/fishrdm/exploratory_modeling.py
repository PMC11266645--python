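"""The exploratory-modeling experiment: sample futures, run all projections.

A *scheme* is one sampled future: an SR parameterisation drawn uniformly
within the published estimate +/- SE bounds plus a climate scenario drawn
uniformly from {moderate, strong}. Schemes are crossed factorially with a
set of sampled policies (constant catches and constant harvest rates), per
SR form, so the full design holds

    total runs = n_forms * n_schemes * n_policies

(the study scale: 2 forms x 200 schemes x 100 policies = 40,000 runs).
The factorial crossing lets every policy be evaluated against the same
futures, which underpins the per-scheme monotone-harm diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import EconParams
from .errors import InvalidArgumentError
from .population_model import (PolicySpec, ProjectionConfig, ReferencePoints,
                               project_batch)
from .sr_models import ENV_FORMS, FORM_PARAMS, SamplingBounds, SRParams
from .synthetic_data import SCENARIOS, SSTTrajectory, StockBiology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertaintyScheme:
    """One sampled future: SR parameterisation + climate scenario."""

    scheme_id: int
    sr_form: str
    params: SRParams
    climate_scenario: str

    def __post_init__(self):
        if self.climate_scenario not in SCENARIOS:
            raise InvalidArgumentError(
                f"unknown scenario {self.climate_scenario!r}")


@dataclass
class ExperimentDesign:
    schemes: Mapping[str, Sequence[UncertaintyScheme]]  # per SR form
    policies: Sequence[PolicySpec]
    seed: int
    config: ProjectionConfig = field(default_factory=ProjectionConfig)

    @property
    def n_runs(self) -> int:
        return sum(len(s) for s in self.schemes.values()) * len(self.policies)


@dataclass
class EnsembleResults:
    """The substrate of all RDM analytics.

    ``long``: one row per run-year (run_id, scheme/policy descriptors, year,
    ssb, fbar, catch, recruits, profit, collapsed). ``summary``: one row per
    run with the scheme parameters, policy, sustainable-year count and the
    all-years success flag.
    """

    long: pd.DataFrame
    summary: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def sample_schemes(form: str, bounds: SamplingBounds, n_schemes: int,
                   seed: int, scenarios: Sequence[str] = SCENARIOS
                   ) -> list[UncertaintyScheme]:
    """Independent uniform draws of SR parameters within their bounds,
    with a climate scenario drawn uniformly per scheme."""
    if n_schemes < 1:
        raise InvalidArgumentError("n_schemes must be >= 1")
    if form not in ENV_FORMS:
        raise InvalidArgumentError(
            f"schemes are sampled for environmental forms, got {form!r}")
    names = FORM_PARAMS[form]
    missing = [p for p in names if p not in bounds.bounds]
    if missing:
        raise InvalidArgumentError(f"bounds missing parameters {missing}")
    if any(bounds.bounds[p][1] - bounds.bounds[p][0] <= 0 for p in names):
        raise InvalidArgumentError("bounds must have positive width")
    rng = np.random.default_rng(seed)
    draws = {p: rng.uniform(*bounds.bounds[p], n_schemes) for p in names}
    scens = rng.choice(list(scenarios), n_schemes)
    out = []
    for i in range(n_schemes):
        kwargs = {p: float(draws[p][i]) for p in names}
        out.append(UncertaintyScheme(scheme_id=i, sr_form=form,
                                     params=SRParams(form=form, **kwargs),
                                     climate_scenario=str(scens[i])))
    return out


def sample_policies(policy_type: str, level_range: tuple[float, float],
                    n_policies: int, seed: int) -> list[PolicySpec]:
    """Uniform draws of the exploitation level within ``level_range``."""
    lo, hi = level_range
    if not (0 <= lo < hi):
        raise InvalidArgumentError("level_range must satisfy 0 <= lo < hi")
    if n_policies < 1:
        raise InvalidArgumentError("n_policies must be >= 1")
    rng = np.random.default_rng(seed)
    levels = rng.uniform(lo, hi, n_policies)
    return [PolicySpec(policy_type, float(v)) for v in levels]


def default_design(bounds_by_form: Mapping[str, SamplingBounds],
                   n_schemes: int = 200, n_policies: int = 100,
                   seed: int = 0,
                   catch_range: tuple[float, float] = (400.0, 200_000.0),
                   rate_range: tuple[float, float] = (0.0002, 0.30),
                   config: ProjectionConfig = ProjectionConfig()
                   ) -> ExperimentDesign:
    """The study design: per-form schemes crossed with a policy set split
    evenly between constant-catch (tonnes) and harvest-rate policies."""
    schemes = {form: sample_schemes(form, bounds_by_form[form], n_schemes,
                                    seed=seed + 1000 + i)
               for i, form in enumerate(ENV_FORMS) if form in bounds_by_form}
    n_catch = n_policies // 2
    policies = (sample_policies("constant_catch", catch_range, n_catch,
                                seed=seed + 2000)
                + sample_policies("harvest_rate", rate_range,
                                  n_policies - n_catch, seed=seed + 2001))
    return ExperimentDesign(schemes=schemes, policies=policies, seed=seed,
                            config=config)


def run_experiments(design: ExperimentDesign, biology: StockBiology,
                    econ: Optional[EconParams],
                    refpts: ReferencePoints,
                    sst_bank: Mapping[str, SSTTrajectory]) -> EnsembleResults:
    """Execute every scheme x policy projection and assemble the ensemble.

    Runs are grouped by (SR form, climate scenario) and dispatched to the
    vectorised batch projector. The summary's ``sustainable_years`` counts
    years meeting both management targets (SSB >= MSY B_trigger and
    fbar <= F_MSY) before any collapse; ``success`` flags runs sustainable
    over the whole horizon.
    """
    config = design.config
    years = config.years
    for scen in SCENARIOS:
        if any(s.climate_scenario == scen
               for ss in design.schemes.values() for s in ss):
            if scen not in sst_bank:
                raise InvalidArgumentError(f"sst_bank missing scenario {scen!r}")

    policies = design.policies
    p_levels = np.array([p.level for p in policies])
    p_is_rate = np.array([p.policy_type == "harvest_rate" for p in policies])

    long_frames, summary_frames = [], []
    run_id0 = 0
    for form, schemes in design.schemes.items():
        scheme_scen = np.array([s.climate_scenario for s in schemes])
        for scen in SCENARIOS:
            idx = np.nonzero(scheme_scen == scen)[0]
            if idx.size == 0:
                continue
            sub = [schemes[i] for i in idx]
            n_s, n_p = len(sub), len(policies)
            # runs ordered scheme-major, policy-minor
            la = np.repeat([s.params.log_alpha for s in sub], n_p)
            dd = np.repeat([s.params.dd_log for s in sub], n_p)
            ga = np.repeat([s.params.gamma for s in sub], n_p)
            sid = np.repeat([s.scheme_id for s in sub], n_p)
            lev = np.tile(p_levels, n_s)
            is_rate = np.tile(p_is_rate, n_s)
            e_run = np.tile(sst_bank[scen].value_in(years), (n_s * n_p, 1))

            logger.info("projecting %d runs: form=%s scenario=%s",
                        n_s * n_p, form, scen)
            res = project_batch(biology, form, la, dd, ga, is_rate, lev,
                                e_run, refpts=refpts, econ=econ,
                                config=config)

            n_runs = n_s * n_p
            run_ids = np.arange(run_id0, run_id0 + n_runs)
            run_id0 += n_runs

            sustainable = ((res.ssb >= refpts.msy_b_trigger)
                           & (res.fbar <= refpts.f_msy)
                           & ~res.collapsed_state)
            sus_years = sustainable.sum(axis=1)
            summary_frames.append(pd.DataFrame({
                "run_id": run_ids, "sr_form": form, "scenario": scen,
                "scheme_id": sid, "policy_type": np.where(
                    is_rate, "harvest_rate", "constant_catch"),
                "level": lev, "log_alpha": la, "dd_log": dd, "gamma": ga,
                "sustainable_years": sus_years,
                "success": sus_years == len(years),
                "collapsed": res.collapsed_state.any(axis=1),
                "infeasible_years": res.infeasible.sum(axis=1),
            }))
            n_years = len(years)
            long_frames.append(pd.DataFrame({
                "run_id": np.repeat(run_ids, n_years),
                "sr_form": form, "scenario": scen,
                "scheme_id": np.repeat(sid, n_years),
                "policy_type": pd.Categorical(np.repeat(
                    np.where(is_rate, "harvest_rate", "constant_catch"),
                    n_years)),
                "level": np.repeat(lev, n_years),
                "year": np.tile(years, n_runs),
                "ssb": res.ssb.ravel(), "fbar": res.fbar.ravel(),
                "catch": res.catch.ravel(), "recruits": res.recruits.ravel(),
                "profit": res.profit.ravel(),
                "collapsed": res.collapsed_state.ravel(),
            }))

    summary = pd.concat(summary_frames, ignore_index=True)
    long = pd.concat(long_frames, ignore_index=True)
    assert len(summary) == design.n_runs, "run-count identity violated"
    provenance = {
        "seed": design.seed,
        "n_runs": design.n_runs,
        "n_policies": len(policies),
        "n_schemes": {f: len(s) for f, s in design.schemes.items()},
        "horizon": [int(years[0]), int(years[-1])],
    }
    return EnsembleResults(long=long, summary=summary, provenance=provenance)


def write_ensemble(ensemble: EnsembleResults, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble.long.to_csv(out / "ensemble_long.csv", index=False)
    ensemble.summary.to_csv(out / "ensemble_summary.csv", index=False)
    with open(out / "design.json", "w") as fh:
        json.dump(ensemble.provenance, fh, indent=2)


def read_ensemble(out_dir) -> EnsembleResults:
    from pathlib import Path

    out = Path(out_dir)
    long = pd.read_csv(out / "ensemble_long.csv")
    summary = pd.read_csv(out / "ensemble_summary.csv")
    with open(out / "design.json") as fh:
        provenance = json.load(fh)
    return EnsembleResults(long=long, summary=summary, provenance=provenance)
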