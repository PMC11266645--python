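"""Synthetic inputs for the full analysis pipeline.

Everything the projection and fitting stages consume can be generated here
with known ground truth: a cod-like age-structured stock biology, a
historical spawning-stock-biomass (SSB) / recruitment / sea-surface-
temperature (SST) series produced by a known stock-recruitment (SR) curve,
SST projections for a moderate and a strong warming scenario, a
price-by-weight table, and a short hindcast of catches used to calibrate the
profitability reference.

Magnitudes emulate North Sea cod: SSB of order 1e5 tonnes, recruitment of
order 1e8-1e9 individuals, individual weights from ~0.1 kg (age 1) to
~10 kg (plus group). The SST variable is an *anomaly* relative to a
reference-period mean, so the e^{-gamma*E} recruitment multiplier is O(1)
when fits and projections use consistent units.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

SCENARIOS = ("moderate", "strong")

# Warming-pathway defaults: anomaly reached by 2100 relative to the
# 2000 baseline, with the strong pathway steepening after the break year.
MODERATE_RISE_2100 = 1.5  # deg C
STRONG_RISE_2100 = 3.5  # deg C
SLOPE_BREAK_YEAR = 2060
SST_AR_COEF = 0.5
SST_NOISE_SD = 0.3  # deg C innovation s.d.

PROJECTION_START = 2030
PROJECTION_END = 2100


@dataclass(frozen=True)
class StockBiology:
    """Fixed biological scaffold of the age-structured projector.

    Ages are consecutive integers; the first class is the recruitment age,
    the last is a plus-group that accumulates survivors. Weights are kg per
    individual, natural mortality is an instantaneous rate per year, and
    selectivity scales fishing mortality per age.
    """

    ages: np.ndarray
    weight_at_age: np.ndarray
    maturity_at_age: np.ndarray
    natural_mortality_at_age: np.ndarray
    selectivity_at_age: np.ndarray
    initial_age_distribution: np.ndarray

    def __post_init__(self):
        n = len(self.ages)
        arrays = (
            self.weight_at_age,
            self.maturity_at_age,
            self.natural_mortality_at_age,
            self.selectivity_at_age,
            self.initial_age_distribution,
        )
        if any(len(a) != n for a in arrays):
            raise InvalidArgumentError("all per-age arrays must share one length")
        if np.any(self.weight_at_age <= 0) or np.any(np.diff(self.weight_at_age) < 0):
            raise InvalidArgumentError("weights must be positive and non-decreasing")
        if np.any(np.diff(self.maturity_at_age) < 0):
            raise InvalidArgumentError("maturity must be non-decreasing with age")
        if np.any((self.maturity_at_age < 0) | (self.maturity_at_age > 1)):
            raise InvalidArgumentError("maturity must lie in [0, 1]")
        if np.any(self.natural_mortality_at_age <= 0):
            raise InvalidArgumentError("natural mortality must be positive")
        if np.any((self.selectivity_at_age < 0) | (self.selectivity_at_age > 1)):
            raise InvalidArgumentError("selectivity must lie in [0, 1]")
        if abs(self.initial_age_distribution.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("initial age distribution must sum to 1")

    @property
    def n_ages(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class ObservedSeries:
    """Annual SSB (t), recruitment (individuals) and SST (anomaly, deg C).

    ``recruits[t]`` is the recruitment produced by ``ssb[t]`` under
    environment ``sst[t]`` (it enters the population the following year).
    ``true_params`` keeps the generating SR hypothesis for recovery tests.
    """

    years: np.ndarray
    ssb: np.ndarray
    recruits: np.ndarray
    sst: np.ndarray
    true_params: Optional[object] = None  # SRParams; avoids circular import

    def __post_init__(self):
        n = len(self.years)
        if not (len(self.ssb) == len(self.recruits) == len(self.sst) == n):
            raise InvalidArgumentError("series arrays must share one length")
        if np.any(np.diff(self.years) != 1):
            raise InvalidArgumentError("years must be consecutive")
        if np.any(self.ssb <= 0):
            raise InvalidArgumentError("ssb must be strictly positive")
        if np.any(self.recruits < 0):
            raise InvalidArgumentError("recruits must be non-negative")


@dataclass(frozen=True)
class SSTTrajectory:
    """One scenario's annual SST anomaly series covering 2030-2100."""

    scenario_id: str
    years: np.ndarray
    sst: np.ndarray

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise InvalidArgumentError(
                f"scenario_id must be one of {SCENARIOS}, got {self.scenario_id!r}"
            )
        if len(self.years) != len(self.sst):
            raise InvalidArgumentError("years and sst must share one length")
        if self.years[0] > PROJECTION_START or self.years[-1] < PROJECTION_END:
            raise InvalidArgumentError(
                "trajectory must cover the projection horizon "
                f"{PROJECTION_START}-{PROJECTION_END}"
            )

    def value_in(self, years: Sequence[int]) -> np.ndarray:
        idx = np.searchsorted(self.years, years)
        if np.any(idx >= len(self.years)) or np.any(self.years[idx] != years):
            raise InvalidArgumentError("requested years outside trajectory span")
        return self.sst[idx]


@dataclass(frozen=True)
class PriceTable:
    """First-sale price (EUR/kg) by individual-weight bin (kg)."""

    weight_bin_edges: np.ndarray
    price_per_kg: np.ndarray

    def __post_init__(self):
        if len(self.weight_bin_edges) != len(self.price_per_kg) + 1:
            raise InvalidArgumentError("need len(edges) == len(prices) + 1")
        if np.any(np.diff(self.weight_bin_edges) <= 0):
            raise InvalidArgumentError("bin edges must be strictly increasing")
        if np.any(self.price_per_kg < 0):
            raise InvalidArgumentError("prices must be non-negative")

    def price_for_weight(self, weight_kg) -> np.ndarray:
        w = np.asarray(weight_kg, dtype=float)
        edges = self.weight_bin_edges
        if np.any(w < edges[0]) or np.any(w > edges[-1]):
            raise InvalidArgumentError(
                f"weight outside price-table range [{edges[0]}, {edges[-1]}] kg"
            )
        idx = np.clip(np.searchsorted(edges, w, side="right") - 1, 0,
                      len(self.price_per_kg) - 1)
        return self.price_per_kg[idx]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_biology(n_ages: int = 6, seed: int = 0) -> StockBiology:
    """Cod-like stock biology for ``n_ages`` age classes (last = plus-group).

    Growth follows a von Bertalanffy weight curve (asymptote ~12-15 kg, so
    age-1 fish weigh a few hundred grams and the plus-group roughly 8-12 kg);
    maturity and gear selectivity are logistic in age; natural mortality
    declines from ~1.0/yr at age 1 (predation on juveniles) to ~0.2/yr; the
    initial age composition is a jittered exponential decline, normalised.
    """
    if n_ages < 3:
        raise InvalidArgumentError("need at least 3 age classes")
    rng = np.random.default_rng(seed)
    ages = np.arange(1, n_ages + 1)

    w_inf = rng.uniform(12.0, 15.0)
    k = rng.uniform(0.18, 0.24)
    t0 = rng.uniform(-0.4, -0.1)
    weight = w_inf * (1.0 - np.exp(-k * (ages - t0))) ** 3

    a50_mat = rng.uniform(2.8, 3.4)
    maturity = 1.0 / (1.0 + np.exp(-2.2 * (ages - a50_mat)))
    a50_sel = rng.uniform(2.0, 2.6)
    selectivity = 1.0 / (1.0 + np.exp(-2.5 * (ages - a50_sel)))

    m1 = rng.uniform(0.9, 1.1)
    m_inf = rng.uniform(0.18, 0.22)
    m = m_inf + (m1 - m_inf) * np.exp(-0.8 * (ages - 1))

    z = rng.uniform(0.7, 0.9)
    dist = np.exp(-z * (ages - 1)) * np.exp(rng.normal(0.0, 0.1, n_ages))
    dist /= dist.sum()

    return StockBiology(
        ages=ages,
        weight_at_age=weight,
        maturity_at_age=np.clip(maturity, 0.0, 1.0),
        natural_mortality_at_age=m,
        selectivity_at_age=np.clip(selectivity, 0.0, 1.0),
        initial_age_distribution=dist,
    )


def generate_historical(
    biology: StockBiology,
    true_params,
    n_years: int = 40,
    noise_sd: float = 0.3,
    seed: int = 0,
    ssb_range: tuple[float, float] = (3.0e4, 3.0e5),
    start_year: int = 1979,
    sst_sd: float = 0.5,
    sst_ar: float = 0.5,
) -> ObservedSeries:
    """Historical series for SR fitting, with known ground truth.

    SSB follows a bounded geometric random walk inside ``ssb_range`` (the
    reflection keeps enough SSB contrast for the density-dependence
    parameter to be identifiable). SST is a stationary AR(1) anomaly.
    Recruitment is the SR curve evaluated at (SSB_t, E_t) times lognormal
    scatter exp(eps_t), eps_t ~ N(0, noise_sd^2).
    """
    from .sr_models import recruitment  # deferred to avoid import cycle

    if n_years < 10:
        raise InvalidArgumentError("need at least 10 years of history")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    lo, hi = ssb_range
    if not (0 < lo < hi):
        raise InvalidArgumentError("ssb_range must satisfy 0 < lo < hi")

    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)

    log_lo, log_hi = np.log(lo), np.log(hi)
    log_ssb = np.empty(n_years)
    log_ssb[0] = rng.uniform(log_lo, log_hi)
    steps = rng.normal(0.0, 0.25, n_years - 1)
    for t in range(1, n_years):
        x = log_ssb[t - 1] + steps[t - 1]
        # reflect at the range boundaries
        while x < log_lo or x > log_hi:
            x = 2 * log_lo - x if x < log_lo else 2 * log_hi - x
        log_ssb[t] = x
    ssb = np.exp(log_ssb)

    innov_sd = sst_sd * np.sqrt(1.0 - sst_ar**2)
    sst = np.empty(n_years)
    sst[0] = rng.normal(0.0, sst_sd)
    for t in range(1, n_years):
        sst[t] = sst_ar * sst[t - 1] + rng.normal(0.0, innov_sd)

    eps = rng.normal(0.0, noise_sd, n_years) if noise_sd > 0 else np.zeros(n_years)
    recruits = recruitment(true_params, ssb, sst) * np.exp(eps)

    return ObservedSeries(years=years, ssb=ssb, recruits=recruits, sst=sst,
                          true_params=true_params)


def _sst_trend(years: np.ndarray, scenario_id: str, start_year: int) -> np.ndarray:
    """Piecewise-linear warming trend (anomaly, deg C)."""
    span = 2100 - start_year
    slope_mod = MODERATE_RISE_2100 / span
    trend = slope_mod * (years - start_year)
    if scenario_id == "strong":
        at_break = slope_mod * (SLOPE_BREAK_YEAR - start_year)
        slope_late = (STRONG_RISE_2100 - at_break) / (2100 - SLOPE_BREAK_YEAR)
        late = years > SLOPE_BREAK_YEAR
        trend = np.where(late, at_break + slope_late * (years - SLOPE_BREAK_YEAR),
                         trend)
    return trend


def generate_sst_projection(
    scenario_id: str,
    seed: int = 0,
    start_year: int = 2000,
    end_year: int = PROJECTION_END,
    noise_sd: float = SST_NOISE_SD,
    ar_coef: float = SST_AR_COEF,
) -> SSTTrajectory:
    """SST projection: piecewise-linear warming trend plus AR(1) noise.

    Both scenarios share the same moderate slope until 2060; the strong
    scenario then steepens towards +3.5 deg C by 2100 (moderate: +1.5).
    The noise stream depends on the seed only, not the scenario, so for a
    fixed seed the strong trajectory dominates the moderate one after the
    slope break by construction. The default span starts in 2000 so the
    series overlaps the historical record for mean bias correction.
    """
    if scenario_id not in SCENARIOS:
        raise InvalidArgumentError(
            f"scenario_id must be one of {SCENARIOS}, got {scenario_id!r}"
        )
    years = np.arange(start_year, end_year + 1)
    trend = _sst_trend(years, scenario_id, start_year)

    rng = np.random.default_rng(seed)
    noise = np.zeros(len(years))
    if noise_sd > 0:
        innov = rng.normal(0.0, noise_sd, len(years))
        noise[0] = innov[0]
        for t in range(1, len(years)):
            noise[t] = ar_coef * noise[t - 1] + innov[t]
    return SSTTrajectory(scenario_id=scenario_id, years=years, sst=trend + noise)


def bias_correct(
    projection: SSTTrajectory,
    reference: ObservedSeries,
    overlap_years: Sequence[int],
) -> SSTTrajectory:
    """Simple mean bias correction of a projection against observations.

    Subtracts the constant offset (projection mean - reference mean) over
    the overlap window from the whole projected series, so the corrected
    series matches the reference mean exactly on the overlap. Idempotent.
    """
    overlap = np.asarray(list(overlap_years))
    if overlap.size == 0:
        raise InvalidArgumentError("overlap_years is empty")
    for years, label in ((projection.years, "projection"), (reference.years, "reference")):
        if not np.all(np.isin(overlap, years)):
            raise InvalidArgumentError(f"overlap years not contained in {label} span")
    proj_mean = projection.value_in(overlap).mean()
    ref_mean = reference.sst[np.isin(reference.years, overlap)].mean()
    return replace(projection, sst=projection.sst - (proj_mean - ref_mean))


def make_price_table() -> PriceTable:
    """Default whitefish-like first-sale price ladder (larger fish dearer)."""
    return PriceTable(
        weight_bin_edges=np.array([0.0, 1.0, 2.0, 4.0, 8.0, 100.0]),
        price_per_kg=np.array([1.2, 1.8, 2.4, 3.0, 3.6]),
    )


def generate_hindcast_catches(
    biology: StockBiology,
    seed: int = 0,
    years: tuple[int, int] = (2000, 2018),
    mean_catch_tonnes: float = 45_000.0,
    cv: float = 0.25,
) -> pd.DataFrame:
    """Annual hindcast catches used to calibrate the profitability reference.

    Total catch is lognormal around ``mean_catch_tonnes`` (the order of the
    fishery's 2000-2018 landings); the age composition of the catch follows
    selectivity times the standing age distribution. Returns one row per
    (year, age) with catch numbers and the total tonnes per year.
    """
    rng = np.random.default_rng(seed)
    yrs = np.arange(years[0], years[1] + 1)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    totals = mean_catch_tonnes * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(yrs)))

    comp = biology.selectivity_at_age * biology.initial_age_distribution
    comp = comp / comp.sum()
    # numbers such that the weight of the age-composed catch hits the total
    mean_w = float(np.sum(comp * biology.weight_at_age))  # kg per fish caught
    rows = []
    for y, tot in zip(yrs, totals):
        n_fish = tot * 1000.0 / mean_w
        for a, age in enumerate(biology.ages):
            rows.append({"year": int(y), "age": int(age),
                         "catch_numbers": n_fish * comp[a],
                         "total_catch_tonnes": tot})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-table round-trip IO
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_biology(biology: StockBiology, path) -> None:
    df = pd.DataFrame({
        "age": biology.ages,
        "weight_kg": biology.weight_at_age,
        "maturity": biology.maturity_at_age,
        "natural_mortality": biology.natural_mortality_at_age,
        "selectivity": biology.selectivity_at_age,
        "initial_fraction": biology.initial_age_distribution,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_biology(path) -> StockBiology:
    df = pd.read_csv(path, float_precision="round_trip")
    return StockBiology(
        ages=df["age"].to_numpy(dtype=int),
        weight_at_age=df["weight_kg"].to_numpy(float),
        maturity_at_age=df["maturity"].to_numpy(float),
        natural_mortality_at_age=df["natural_mortality"].to_numpy(float),
        selectivity_at_age=df["selectivity"].to_numpy(float),
        initial_age_distribution=df["initial_fraction"].to_numpy(float),
    )


def write_series(series: ObservedSeries, path) -> None:
    """Series table, one row per year; ground-truth SR params go into
    ``# key=value`` header comments so the file round-trips losslessly."""
    lines = []
    if series.true_params is not None:
        p = series.true_params
        lines.append(f"# true_form={p.form}")
        lines.append(f"# true_log_alpha={p.log_alpha!r}")
        lines.append(f"# true_dd_log={p.dd_log!r}")
        lines.append(f"# true_gamma={p.gamma!r}")
        if p.break_ssb is not None:
            lines.append(f"# true_break_ssb={p.break_ssb!r}")
    df = pd.DataFrame({"year": series.years, "ssb_tonnes": series.ssb,
                       "recruits": series.recruits, "sst_anomaly": series.sst})
    body = df.to_csv(index=False, float_format=_FLOAT_FMT)
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in lines) + body)


def read_series(path) -> ObservedSeries:
    from .sr_models import SRParams

    meta = {}
    with open(path) as fh:
        text = fh.readlines()
    for line in text:
        if line.startswith("# "):
            key, _, val = line[2:].strip().partition("=")
            meta[key] = val
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    true_params = None
    if "true_form" in meta:
        true_params = SRParams(
            form=meta["true_form"],
            log_alpha=float(meta["true_log_alpha"]),
            dd_log=float(meta["true_dd_log"]),
            gamma=float(meta["true_gamma"]),
            break_ssb=float(meta["true_break_ssb"]) if "true_break_ssb" in meta else None,
        )
    return ObservedSeries(
        years=df["year"].to_numpy(int),
        ssb=df["ssb_tonnes"].to_numpy(float),
        recruits=df["recruits"].to_numpy(float),
        sst=df["sst_anomaly"].to_numpy(float),
        true_params=true_params,
    )


def write_sst(trajectories: Sequence[SSTTrajectory], path) -> None:
    frames = [pd.DataFrame({"year": t.years, "scenario": t.scenario_id,
                            "sst_anomaly": t.sst}) for t in trajectories]
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sst(path) -> dict[str, SSTTrajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for scen, grp in df.groupby("scenario"):
        grp = grp.sort_values("year")
        out[str(scen)] = SSTTrajectory(scenario_id=str(scen),
                                       years=grp["year"].to_numpy(int),
                                       sst=grp["sst_anomaly"].to_numpy(float))
    return out


def write_prices(prices: PriceTable, path) -> None:
    df = pd.DataFrame({
        "bin_lower_kg": prices.weight_bin_edges[:-1],
        "bin_upper_kg": prices.weight_bin_edges[1:],
        "eur_per_kg": prices.price_per_kg,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_prices(path) -> PriceTable:
    df = pd.read_csv(path, float_precision="round_trip")
    edges = np.append(df["bin_lower_kg"].to_numpy(float),
                      df["bin_upper_kg"].to_numpy(float)[-1])
    return PriceTable(weight_bin_edges=edges,
                      price_per_kg=df["eur_per_kg"].to_numpy(float))
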