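"""Age-structured annual projection of the stock under a fixed policy.

The projector iterates a standard assessment-style recursion over the
2030-2100 horizon: spawning-stock biomass (SSB) is measured at the start of
the year before fishing; the policy (constant catch in tonnes, or constant
harvest rate as a fraction of start-of-year total biomass) is translated to
a fishing-mortality multiplier F by inverting the Baranov catch equation
with bisection; cohorts then survive exp(-F*sel_a - M_a), the oldest class
accumulating survivors as a plus-group; and next year's age-1 numbers come
from the stock-recruitment curve evaluated at this year's SSB and SST.

If SSB falls below a collapse threshold (default 10% of MSY B_trigger) the
stock is flagged collapsed and fishing is terminated for all remaining
years.

A vectorised batch engine (`project_batch`) runs many parameterisations and
policies simultaneously; `project` is the single-run interface with an
identical recursion, used by the tests as a cross-check of the batch path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, NoSolutionError
from .synthetic_data import (PROJECTION_END, PROJECTION_START, SSTTrajectory,
                             StockBiology)
from .sr_models import SRParams, recruitment

KG_PER_TONNE = 1000.0


@dataclass(frozen=True)
class StockState:
    """Numbers at age at the start of one calendar year."""

    year: int
    numbers_at_age: np.ndarray

    def __post_init__(self):
        if np.any(self.numbers_at_age < 0):
            raise InvalidArgumentError("numbers at age must be non-negative")


@dataclass(frozen=True)
class PolicySpec:
    """A management decision held fixed over the whole projection."""

    policy_type: str  # constant_catch | harvest_rate
    level: float  # tonnes/yr or fraction of start-of-year total biomass

    def __post_init__(self):
        if self.policy_type not in ("constant_catch", "harvest_rate"):
            raise InvalidArgumentError(
                f"unknown policy_type {self.policy_type!r}")
        if self.level < 0:
            raise InvalidArgumentError("policy level must be non-negative")
        if self.policy_type == "harvest_rate" and self.level > 1:
            raise InvalidArgumentError("harvest rate must lie in [0, 1]")


@dataclass(frozen=True)
class ReferencePoints:
    """MSY reference points of the assessed stock."""

    f_msy: float = 0.28
    msy_b_trigger: float = 97_800.0  # tonnes

    def __post_init__(self):
        if self.f_msy <= 0 or self.msy_b_trigger <= 0:
            raise InvalidArgumentError("reference points must be positive")


@dataclass(frozen=True)
class ProjectionConfig:
    """Numerical and convention choices of the projector."""

    f_cap: float = 3.0  # upper bound of the F bisection (per year)
    fbar_ages: tuple[int, int] = (2, 4)  # inclusive reference-age window
    collapse_fraction: float = 0.1  # of MSY B_trigger
    start_year: int = PROJECTION_START
    end_year: int = PROJECTION_END
    f_tol: float = 1e-6  # relative tolerance of the catch inversion

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


@dataclass
class RunResult:
    """Annual outcome series of one projection, plus collapse diagnostics."""

    years: np.ndarray
    ssb: np.ndarray  # tonnes, start of year
    fbar: np.ndarray  # mean F over reference ages
    catch: np.ndarray  # realized catch, tonnes
    recruits: np.ndarray  # age-1 numbers present in each year
    profit: np.ndarray  # EUR per year (zeros if no economics supplied)
    collapsed: bool
    collapse_year: Optional[int]
    catch_infeasible_years: list


def ssb_of(state_or_numbers, biology: StockBiology) -> float:
    """Spawning-stock biomass in tonnes: sum_a N_a * w_a * maturity_a."""
    n = getattr(state_or_numbers, "numbers_at_age", state_or_numbers)
    n = np.asarray(n, float)
    if n.shape[-1] != biology.n_ages:
        raise InvalidArgumentError("age dimension does not match biology")
    return float(np.sum(n * biology.weight_at_age * biology.maturity_at_age)
                 / KG_PER_TONNE)


def total_biomass(numbers, biology: StockBiology) -> float:
    return float(np.sum(np.asarray(numbers, float) * biology.weight_at_age)
                 / KG_PER_TONNE)


def baranov_catch(numbers, biology: StockBiology, f: float) -> float:
    """Catch weight (tonnes) taken at fishing-mortality multiplier ``f``.

    C = sum_a F_a/Z_a * N_a * (1 - e^{-Z_a}) * w_a with F_a = f * sel_a and
    Z_a = F_a + M_a.
    """
    fa = f * biology.selectivity_at_age
    z = fa + biology.natural_mortality_at_age
    catch_n = (fa / z) * np.asarray(numbers, float) * (1.0 - np.exp(-z))
    return float(np.sum(catch_n * biology.weight_at_age) / KG_PER_TONNE)


def baranov_catch_numbers(numbers, biology: StockBiology, f: float) -> np.ndarray:
    fa = f * biology.selectivity_at_age
    z = fa + biology.natural_mortality_at_age
    return (fa / z) * np.asarray(numbers, float) * (1.0 - np.exp(-z))


def solve_f_for_catch(state, biology: StockBiology, target_catch: float,
                      f_cap: float = 3.0, tol: float = 1e-6
                      ) -> tuple[float, float, bool]:
    """Invert the Baranov equation for F by bisection on [0, f_cap].

    Returns ``(f, attained_catch, feasible)``. If the target exceeds the
    catch attainable at ``f_cap`` the cap is returned with feasible=False.
    """
    if target_catch < 0:
        raise InvalidArgumentError("target catch must be non-negative")
    numbers = getattr(state, "numbers_at_age", state)
    if target_catch == 0:
        return 0.0, 0.0, True
    c_max = baranov_catch(numbers, biology, f_cap)
    if target_catch > c_max:
        return f_cap, c_max, False
    lo, hi = 0.0, f_cap
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c_mid = baranov_catch(numbers, biology, mid)
        if c_mid < target_catch:
            lo = mid
        else:
            hi = mid
        if abs(c_mid - target_catch) <= tol * target_catch:
            return mid, c_mid, True
    mid = 0.5 * (lo + hi)
    return mid, baranov_catch(numbers, biology, mid), True


def _fbar(f: float, biology: StockBiology, fbar_ages: tuple[int, int]) -> float:
    mask = (biology.ages >= fbar_ages[0]) & (biology.ages <= fbar_ages[1])
    if not mask.any():
        raise InvalidArgumentError("no ages in the fbar reference window")
    return float(np.mean(f * biology.selectivity_at_age[mask]))


def initialize_stock(biology: StockBiology, target_ssb: float,
                     year: int = PROJECTION_START) -> StockState:
    """Scale the reference age composition so SSB equals ``target_ssb``."""
    if target_ssb <= 0:
        raise InvalidArgumentError("target SSB must be positive")
    unit_ssb = ssb_of(biology.initial_age_distribution, biology)
    if unit_ssb <= 0:
        raise NoSolutionError("reference age distribution has no mature biomass")
    return StockState(year=year,
                      numbers_at_age=biology.initial_age_distribution
                      * (target_ssb / unit_ssb))


def step(state: StockState, biology: StockBiology, sr: SRParams,
         policy: PolicySpec, e_t: float,
         config: ProjectionConfig = ProjectionConfig()
         ) -> tuple[StockState, dict]:
    """Advance the stock one year under the policy; return the year record."""
    n = state.numbers_at_age
    ssb_t = ssb_of(n, biology)
    tb_t = total_biomass(n, biology)
    if policy.policy_type == "constant_catch":
        target = policy.level
    else:
        target = policy.level * tb_t
    f, attained, feasible = solve_f_for_catch(n, biology, target,
                                              f_cap=config.f_cap,
                                              tol=config.f_tol)
    catch_numbers = baranov_catch_numbers(n, biology, f)
    z = f * biology.selectivity_at_age + biology.natural_mortality_at_age
    survivors = n * np.exp(-z)
    nxt = np.empty_like(n)
    nxt[1:] = survivors[:-1]
    nxt[-1] += survivors[-1]  # plus-group accumulates
    nxt[0] = recruitment(sr, ssb_t, e_t)
    record = {
        "year": state.year,
        "ssb": ssb_t,
        "total_biomass": tb_t,
        "fbar": _fbar(f, biology, config.fbar_ages),
        "f_multiplier": f,
        "catch": attained,
        "catch_numbers_at_age": catch_numbers,
        "recruits": float(n[0]),
        "feasible": feasible,
    }
    return StockState(year=state.year + 1, numbers_at_age=nxt), record


def project(biology: StockBiology, sr: SRParams, policy: PolicySpec,
            sst: SSTTrajectory, refpts: ReferencePoints = ReferencePoints(),
            econ=None, config: ProjectionConfig = ProjectionConfig(),
            initial_ssb: Optional[float] = None) -> RunResult:
    """Project the stock over the full horizon under one fixed policy.

    The stock starts at ``initial_ssb`` (default: MSY B_trigger). When SSB
    drops below ``collapse_fraction * msy_b_trigger`` the run is flagged
    collapsed and fishing is terminated (zero catch) for all later years.
    Profit per year is appended when an economics parameter set is given.
    """
    from . import economics  # deferred import keeps module layering acyclic

    years = config.years
    e = sst.value_in(years)
    state = initialize_stock(biology, initial_ssb or refpts.msy_b_trigger,
                             year=config.start_year)
    n_years = len(years)
    out = {k: np.zeros(n_years) for k in
           ("ssb", "fbar", "catch", "recruits", "profit")}
    collapsed = False
    collapse_year = None
    infeasible = []
    threshold = config.collapse_fraction * refpts.msy_b_trigger
    zero_policy = PolicySpec(policy.policy_type, 0.0)
    for i, year in enumerate(years):
        if not collapsed and ssb_of(state, biology) < threshold:
            collapsed = True
            collapse_year = int(year)
        active_policy = zero_policy if collapsed else policy
        state, rec = step(state, biology, sr, active_policy, e[i], config)
        out["ssb"][i] = rec["ssb"]
        out["fbar"][i] = rec["fbar"]
        out["catch"][i] = rec["catch"]
        out["recruits"][i] = rec["recruits"]
        if econ is not None:
            out["profit"][i] = economics.profit(rec, biology, econ)
        if not rec["feasible"]:
            infeasible.append(int(year))
    return RunResult(years=years, ssb=out["ssb"], fbar=out["fbar"],
                     catch=out["catch"], recruits=out["recruits"],
                     profit=out["profit"], collapsed=collapsed,
                     collapse_year=collapse_year,
                     catch_infeasible_years=infeasible)


# ---------------------------------------------------------------------------
# Vectorised batch engine
# ---------------------------------------------------------------------------

@dataclass
class BatchResult:
    """Per-run-by-year outcome arrays for a batch of projections.

    Arrays are shaped (n_runs, n_years); ``collapsed_state`` marks, per run
    and year, whether the collapse rule was already in force that year.
    """

    years: np.ndarray
    ssb: np.ndarray
    fbar: np.ndarray
    catch: np.ndarray
    recruits: np.ndarray
    profit: np.ndarray
    collapsed_state: np.ndarray  # boolean
    infeasible: np.ndarray  # boolean


def _batch_recruitment(form: str, log_alpha, dd_log, gamma, ssb, e):
    alpha = np.exp(log_alpha)
    if form in ("env_ricker", "ricker"):
        g = gamma if form == "env_ricker" else 0.0
        return alpha * ssb * np.exp(-ssb * np.exp(-dd_log) - g * e)
    if form in ("env_beverton_holt", "beverton_holt"):
        g = gamma if form == "env_beverton_holt" else 0.0
        return np.exp(-g * e) * alpha * ssb / (1.0 + np.exp(dd_log) * ssb)
    raise InvalidArgumentError(f"batch engine does not support form {form!r}")


def project_batch(biology: StockBiology, form: str,
                  log_alpha: np.ndarray, dd_log: np.ndarray,
                  gamma: np.ndarray, policy_is_rate: np.ndarray,
                  level: np.ndarray, e_by_run: np.ndarray,
                  refpts: ReferencePoints = ReferencePoints(),
                  econ=None, config: ProjectionConfig = ProjectionConfig(),
                  initial_ssb: Optional[float] = None,
                  n_bisect: int = 60) -> BatchResult:
    """Run many projections of one SR form simultaneously.

    Parameters are vectors over runs; ``e_by_run`` is the (n_runs, n_years)
    SST forcing. The recursion is identical to `project`, with the Baranov
    inversion done as a fixed-iteration bisection vectorised across runs.
    """
    from . import economics

    years = config.years
    n_years = len(years)
    log_alpha, dd_log, gamma, level = map(
        lambda v: np.asarray(v, float), (log_alpha, dd_log, gamma, level))
    policy_is_rate = np.asarray(policy_is_rate, bool)
    n_runs = len(level)
    if e_by_run.shape != (n_runs, n_years):
        raise InvalidArgumentError("e_by_run must be (n_runs, n_years)")

    w = biology.weight_at_age
    mat = biology.maturity_at_age
    sel = biology.selectivity_at_age
    m = biology.natural_mortality_at_age
    init = initialize_stock(biology, initial_ssb or refpts.msy_b_trigger)
    n = np.tile(init.numbers_at_age, (n_runs, 1))

    fmask = (biology.ages >= config.fbar_ages[0]) & \
            (biology.ages <= config.fbar_ages[1])
    sel_fbar_mean = sel[fmask].mean()
    threshold = config.collapse_fraction * refpts.msy_b_trigger

    if econ is not None:
        price_at_age = econ.price_table.price_for_weight(w)

    ssb_o = np.zeros((n_runs, n_years))
    fbar_o = np.zeros((n_runs, n_years))
    catch_o = np.zeros((n_runs, n_years))
    rec_o = np.zeros((n_runs, n_years))
    profit_o = np.zeros((n_runs, n_years))
    collapsed_o = np.zeros((n_runs, n_years), dtype=bool)
    infeasible_o = np.zeros((n_runs, n_years), dtype=bool)
    collapsed = np.zeros(n_runs, dtype=bool)

    def batch_catch(numbers, f):
        fa = f[:, None] * sel[None, :]
        z = fa + m[None, :]
        catch_n = (fa / z) * numbers * (1.0 - np.exp(-z))
        return catch_n, (catch_n * w[None, :]).sum(axis=1) / KG_PER_TONNE

    for i in range(n_years):
        ssb_t = (n * w * mat).sum(axis=1) / KG_PER_TONNE
        tb_t = (n * w).sum(axis=1) / KG_PER_TONNE
        collapsed |= ssb_t < threshold
        target = np.where(policy_is_rate, level * tb_t, level)
        target = np.where(collapsed, 0.0, target)

        _, c_max = batch_catch(n, np.full(n_runs, config.f_cap))
        feasible = target <= c_max
        f = np.full(n_runs, config.f_cap)
        solve = feasible & (target > 0)
        lo = np.zeros(n_runs)
        hi = np.full(n_runs, config.f_cap)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            _, c_mid = batch_catch(n, mid)
            below = c_mid < target
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        f = np.where(solve, 0.5 * (lo + hi), f)
        f = np.where(target <= 0, 0.0, f)

        catch_n, catch_t = batch_catch(n, f)
        z = f[:, None] * sel[None, :] + m[None, :]
        survivors = n * np.exp(-z)
        nxt = np.empty_like(n)
        nxt[:, 1:] = survivors[:, :-1]
        nxt[:, -1] += survivors[:, -1]
        nxt[:, 0] = _batch_recruitment(form, log_alpha, dd_log, gamma,
                                       ssb_t, e_by_run[:, i])

        ssb_o[:, i] = ssb_t
        fbar_o[:, i] = f * sel_fbar_mean
        catch_o[:, i] = catch_t
        rec_o[:, i] = n[:, 0]
        collapsed_o[:, i] = collapsed
        infeasible_o[:, i] = ~feasible
        if econ is not None:
            revenue = (catch_n * w[None, :] * price_at_age[None, :]).sum(axis=1)
            profit_o[:, i] = revenue - econ.cost_scale * catch_t ** econ.cost_exponent
        n = nxt

    return BatchResult(years=years, ssb=ssb_o, fbar=fbar_o, catch=catch_o,
                       recruits=rec_o, profit=profit_o,
                       collapsed_state=collapsed_o, infeasible=infeasible_o)
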