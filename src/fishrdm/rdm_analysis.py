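"""RDM analytics on the ensemble: feature scoring, scenario discovery,
risk curves, trade-offs and temporal risk dynamics.

Management success in a year means both MSY targets hold: SSB >= MSY
B_trigger and fbar <= F_MSY; a year violates sustainability when either
fails (the strict complement, so success and violation partition every
year). Years from a stock collapse onward never count as successful: the
collapse rule terminates fishing permanently, and a collapsed-then-
rebuilding stock with F = 0 is a management failure, not a success.

Sustainability risk of a policy bin is the percentage of its runs with any
violating year in the period of interest; profitability risk is the
percentage of runs whose profit drops below the historical reference in
any year of the period (a period-mean convention is available as a
switch). Periods follow the mid-century (2030-2049) / end-of-century
(2050-2099) split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.inspection import partial_dependence

from .economics import EconParams
from .errors import InvalidArgumentError
from .population_model import ReferencePoints, RunResult

PERIODS: dict[str, tuple[int, int]] = {
    "mid_century": (2030, 2049),
    "end_of_century": (2050, 2099),
    "full": (2030, 2100),
}

PREDICTORS = ("level", "log_alpha", "dd_log", "gamma", "scenario_strong")


@dataclass(frozen=True)
class GBRConfig:
    """Boosted-trees hyperparameters (library defaults, pinned)."""

    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    random_state: int = 0
    pd_grid_resolution: int = 20


@dataclass
class FeatureScores:
    importances: pd.Series  # share per predictor, sums to 1
    partial_dependence: dict  # (x, y) -> {"grid_x", "grid_y", "values"}


@dataclass
class RiskCurve:
    policy_type: str
    period: str
    table: pd.DataFrame  # bin_left, bin_right, level, sustainability/profitability risk, n_runs


def sustainable_years(run: RunResult, refpts: ReferencePoints) -> int:
    """Years meeting both targets (SSB >= trigger, fbar <= F_MSY) before
    any collapse."""
    ok = (run.ssb >= refpts.msy_b_trigger) & (run.fbar <= refpts.f_msy)
    if run.collapse_year is not None:
        ok &= run.years < run.collapse_year
    return int(ok.sum())


def _violation_mask(long: pd.DataFrame, refpts: ReferencePoints,
                    which: str = "both") -> np.ndarray:
    """Per-row sustainability violation, optionally restricted to the F or
    SSB condition (the decomposition used for zero-catch diagnostics)."""
    f_bad = long["fbar"].to_numpy() > refpts.f_msy
    b_bad = long["ssb"].to_numpy() < refpts.msy_b_trigger
    if which == "both":
        return f_bad | b_bad | long["collapsed"].to_numpy()
    if which == "f":
        return f_bad
    if which == "ssb":
        return b_bad
    raise InvalidArgumentError("which must be 'both', 'f' or 'ssb'")


def _period_slice(long: pd.DataFrame, period: str) -> pd.DataFrame:
    if period not in PERIODS:
        raise InvalidArgumentError(f"unknown period {period!r}")
    lo, hi = PERIODS[period]
    yr = long["year"]
    return long[(yr >= lo) & (yr <= hi)]


def _runs_violating(long: pd.DataFrame, refpts: ReferencePoints, period: str,
                    which: str = "both") -> pd.Series:
    """Boolean per run_id: any violating year within the period."""
    sub = _period_slice(long, period)
    viol = pd.Series(_violation_mask(sub, refpts, which), index=sub.index)
    return viol.groupby(sub["run_id"]).any()


def _runs_below_reference(long: pd.DataFrame, econ: EconParams, period: str,
                          convention: str = "any_year") -> pd.Series:
    sub = _period_slice(long, period)
    grouped = sub.groupby("run_id")["profit"]
    if convention == "any_year":
        return grouped.min() < econ.reference_profit
    if convention == "period_mean":
        return grouped.mean() < econ.reference_profit
    raise InvalidArgumentError("convention must be 'any_year' or 'period_mean'")


def sustainability_risk(ensemble, refpts: ReferencePoints,
                        run_ids: Sequence[int], period: str = "full",
                        which: str = "both") -> float:
    """% of the given runs with any sustainability violation in the period,
    pooled over climate scenarios."""
    run_ids = np.asarray(list(run_ids))
    if run_ids.size == 0:
        raise InvalidArgumentError("empty policy bin")
    long = ensemble.long[ensemble.long["run_id"].isin(run_ids)]
    viol = _runs_violating(long, refpts, period, which)
    return 100.0 * float(viol.mean())


def profitability_risk(ensemble, econ: EconParams,
                       run_ids: Sequence[int], period: str = "full",
                       convention: str = "any_year") -> float:
    """% of the given runs whose profit falls below the reference."""
    run_ids = np.asarray(list(run_ids))
    if run_ids.size == 0:
        raise InvalidArgumentError("empty policy bin")
    long = ensemble.long[ensemble.long["run_id"].isin(run_ids)]
    below = _runs_below_reference(long, econ, period, convention)
    return 100.0 * float(below.mean())


def _policy_bins(levels: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = levels.min(), levels.max()
    if hi <= lo:
        raise InvalidArgumentError("cannot bin a single policy level")
    return np.linspace(lo, hi * (1 + 1e-12), n_bins + 1)


def risk_curve(ensemble, refpts: ReferencePoints, econ: Optional[EconParams],
               policy_type: str, period: str = "full", n_bins: int = 25,
               profit_convention: str = "any_year") -> RiskCurve:
    """Binned sustainability (and profitability) risk along the policy grid."""
    summary = ensemble.summary
    stratum = summary[summary["policy_type"] == policy_type]
    if len(stratum) == 0:
        raise InvalidArgumentError(f"no runs of policy_type {policy_type!r}")
    levels = stratum["level"].to_numpy()
    edges = _policy_bins(levels, n_bins)
    long = ensemble.long[ensemble.long["run_id"].isin(stratum["run_id"])]
    sus = _runs_violating(long, refpts, period)
    prof = (_runs_below_reference(long, econ, period, profit_convention)
            if econ is not None else None)
    run_level = stratum.set_index("run_id")["level"]
    which_bin = np.digitize(run_level.to_numpy(), edges) - 1

    rows = []
    for b in range(n_bins):
        ids = run_level.index[which_bin == b]
        row = {"bin_left": edges[b], "bin_right": edges[b + 1],
               "level": 0.5 * (edges[b] + edges[b + 1]), "n_runs": len(ids)}
        if len(ids) == 0:
            row["sustainability_risk"] = np.nan
            row["profitability_risk"] = np.nan
        else:
            row["sustainability_risk"] = 100.0 * float(sus.loc[ids].mean())
            row["profitability_risk"] = (100.0 * float(prof.loc[ids].mean())
                                         if prof is not None else np.nan)
        rows.append(row)
    return RiskCurve(policy_type=policy_type, period=period,
                     table=pd.DataFrame(rows))


def feature_scores(ensemble, sr_form: str, policy_type: str,
                   config: GBRConfig = GBRConfig()) -> FeatureScores:
    """Gradient-boosted regression trees on sustainable-year counts.

    Target: per-run sustainable_years; predictors: policy level, the three
    SR parameters and a strong-scenario indicator. Importances are the
    tree ensemble's normalised impurity reductions; two-dimensional
    partial-dependence surfaces are returned for (level x log_alpha) and
    (level x gamma).
    """
    summary = ensemble.summary
    stratum = summary[(summary["sr_form"] == sr_form)
                      & (summary["policy_type"] == policy_type)]
    if len(stratum) == 0:
        raise InvalidArgumentError(
            f"ensemble has no runs for {sr_form!r} / {policy_type!r}")
    X = pd.DataFrame({
        "level": stratum["level"],
        "log_alpha": stratum["log_alpha"],
        "dd_log": stratum["dd_log"],
        "gamma": stratum["gamma"],
        "scenario_strong": (stratum["scenario"] == "strong").astype(float),
    })
    y = stratum["sustainable_years"].to_numpy(float)
    model = GradientBoostingRegressor(
        n_estimators=config.n_estimators, learning_rate=config.learning_rate,
        max_depth=config.max_depth, random_state=config.random_state)
    model.fit(X, y)
    imp = model.feature_importances_
    total = imp.sum()
    shares = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))
    importances = pd.Series(shares, index=list(X.columns))

    pd_surfaces = {}
    for pair in (("level", "log_alpha"), ("level", "gamma")):
        cols = [X.columns.get_loc(c) for c in pair]
        res = partial_dependence(model, X, features=[tuple(cols)],
                                 grid_resolution=config.pd_grid_resolution)
        pd_surfaces[pair] = {"grid_x": res["grid_values"][0],
                             "grid_y": res["grid_values"][1],
                             "values": res["average"][0]}
    return FeatureScores(importances=importances, partial_dependence=pd_surfaces)


def discover_successful(ensemble, refpts: ReferencePoints,
                        n_bins: int = 25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Runs meeting both targets every projection year, with a per-policy-bin
    success-frequency characterisation table."""
    summary = ensemble.summary
    subset = summary[summary["success"]].copy()
    char_rows = []
    for ptype, stratum in summary.groupby("policy_type"):
        levels = stratum["level"].to_numpy()
        if levels.max() > levels.min():
            edges = _policy_bins(levels, n_bins)
            which = np.digitize(levels, edges) - 1
            for b in range(n_bins):
                mask = which == b
                if mask.sum() == 0:
                    continue
                char_rows.append({
                    "policy_type": ptype, "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "level": 0.5 * (edges[b] + edges[b + 1]),
                    "n_runs": int(mask.sum()),
                    "success_pct": 100.0 * float(
                        stratum["success"].to_numpy()[mask].mean()),
                })
    return subset, pd.DataFrame(char_rows)


def tradeoff(ensemble, refpts: ReferencePoints, econ: EconParams,
             policy_type: str, period: str = "full", n_bins: int = 25,
             profit_convention: str = "any_year"
             ) -> tuple[RiskCurve, dict]:
    """Risk pairs along the policy grid with the two highlighted levels:
    the grid level minimising summed risk, and the level whose
    sustainability/profitability risk ratio is nearest 1."""
    curve = risk_curve(ensemble, refpts, econ, policy_type, period, n_bins,
                       profit_convention)
    t = curve.table.dropna(subset=["sustainability_risk",
                                   "profitability_risk"])
    s = t["sustainability_risk"].to_numpy()
    p = t["profitability_risk"].to_numpy()
    summed = s + p
    eps = 1e-12  # guard: a zero risk only wins the ratio if both are zero
    ratio_dist = np.abs(np.log((s + eps) / (p + eps)))
    sel = {
        "min_sum_level": float(t["level"].iloc[int(np.argmin(summed))]),
        "min_sum_risks": (float(s[np.argmin(summed)]),
                          float(p[np.argmin(summed)])),
        "ratio_one_level": float(t["level"].iloc[int(np.argmin(ratio_dist))]),
        "ratio_one_risks": (float(s[np.argmin(ratio_dist)]),
                            float(p[np.argmin(ratio_dist)])),
    }
    return curve, sel


def temporal_risk(ensemble, refpts: ReferencePoints,
                  econ: Optional[EconParams], policy_type: str,
                  kind: str = "sustainability"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-policy, per-year risk series and 25/50/75-percentile envelopes.

    For each policy (unique sampled level) and year, the % of that policy's
    runs violating the chosen condition in that year; the envelope tables
    summarise the distribution of those series across policies.
    """
    summary = ensemble.summary
    stratum = summary[summary["policy_type"] == policy_type]
    if len(stratum) == 0:
        raise InvalidArgumentError(f"no runs of policy_type {policy_type!r}")
    long = ensemble.long[ensemble.long["run_id"].isin(stratum["run_id"])].copy()
    if kind == "sustainability":
        long["viol"] = _violation_mask(long, refpts)
    elif kind == "profitability":
        if econ is None:
            raise InvalidArgumentError("profitability risk needs economics")
        long["viol"] = long["profit"].to_numpy() < econ.reference_profit
    else:
        raise InvalidArgumentError("kind must be sustainability|profitability")
    per_policy = (long.groupby(["level", "year"])["viol"].mean() * 100.0
                  ).rename("risk_pct").reset_index()
    env = (per_policy.groupby("year")["risk_pct"]
           .quantile([0.25, 0.5, 0.75]).unstack())
    env.columns = ["q25", "median", "q75"]
    return per_policy, env.reset_index()
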