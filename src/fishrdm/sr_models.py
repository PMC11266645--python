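"""Stock-recruitment (SR) models, fitting, and uniform sampling bounds.

Two environmentally sensitive SR forms drive the projections:

* environmental Beverton-Holt:  R = e^{-gamma E} * alpha S / (1 + beta S)
* environmental Ricker:         R = alpha S e^{-beta S - gamma E}

with S = spawning-stock biomass (tonnes), E = SST anomaly (deg C),
alpha = initial slope (recruits per tonne of SSB), beta the density
dependence, gamma >= 0 the strength of the negative temperature effect.
Climate-insensitive variants drop the gamma term; the hockey-stick
comparator is R = alpha * min(S, break_ssb), the piecewise-linear form used
in operational assessment advice.

Parameterization
----------------
SSB-related parameters are carried on the log scale so that fitting and
uniform sampling can never produce biologically meaningless negative
values. ``log_alpha`` is ln(alpha). ``dd_log`` houses the density
dependence: for the Beverton-Holt family beta = exp(dd_log) (per tonne,
dd_log around -11), while for the Ricker family dd_log is the log of the
density-dependence *scale* in tonnes, i.e. the Ricker exponent is
-S / exp(dd_log), equivalently beta = exp(-dd_log) (dd_log around 12, a
scale of roughly 2e5 t). This makes both families dimensionally sensible
at cod-like SSB magnitudes. For the hockey stick, dd_log = ln(break_ssb).

Fitting maximises the lognormal likelihood of recruitment (least squares
on log recruits); standard errors come from the curvature of the objective
at the optimum, and the estimate +/- SE interval supplies the bounds of the
uniform distributions sampled by the exploratory ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitFailureError, InvalidArgumentError
from .synthetic_data import ObservedSeries

ENV_FORMS = ("env_ricker", "env_beverton_holt")
ALL_FORMS = ("env_ricker", "env_beverton_holt", "ricker", "beverton_holt",
             "hockey_stick")

#: free parameters per form, in fit order
FORM_PARAMS: dict[str, tuple[str, ...]] = {
    "env_ricker": ("log_alpha", "dd_log", "gamma"),
    "env_beverton_holt": ("log_alpha", "dd_log", "gamma"),
    "ricker": ("log_alpha", "dd_log"),
    "beverton_holt": ("log_alpha", "dd_log"),
    "hockey_stick": ("log_alpha", "dd_log"),
}


@dataclass(frozen=True)
class SRParams:
    """One SR hypothesis: functional form plus log-scale parameters."""

    form: str
    log_alpha: float
    dd_log: float
    gamma: float = 0.0
    break_ssb: Optional[float] = None

    def __post_init__(self):
        if self.form not in ALL_FORMS:
            raise InvalidArgumentError(f"unknown SR form {self.form!r}")
        if self.form == "hockey_stick":
            brk = self.break_ssb
            if brk is None:
                object.__setattr__(self, "break_ssb", float(np.exp(self.dd_log)))
            elif brk <= 0:
                raise InvalidArgumentError("break_ssb must be positive")

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))

    @property
    def beta(self) -> float:
        """Density dependence on the natural scale of the form's equation."""
        if self.form in ("env_ricker", "ricker"):
            return float(np.exp(-self.dd_log))
        if self.form in ("env_beverton_holt", "beverton_holt"):
            return float(np.exp(self.dd_log))
        raise InvalidArgumentError("hockey stick has no beta; use break_ssb")


@dataclass(frozen=True)
class FittedSR:
    """Point estimates with standard errors and fit-quality summaries."""

    params: SRParams
    standard_errors: Mapping[str, float]
    aic: float
    deviance_explained: float
    n_obs: int

    def __post_init__(self):
        if any(se <= 0 for se in self.standard_errors.values()):
            raise InvalidArgumentError("standard errors must be positive")
        if self.deviance_explained > 1:
            raise InvalidArgumentError("deviance explained cannot exceed 1")


@dataclass(frozen=True)
class SamplingBounds:
    """Per-parameter (lower, upper) = estimate -/+ SE, for uniform sampling."""

    form: str
    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise InvalidArgumentError(f"bounds for {name} must satisfy lo < hi")


def recruitment(params: SRParams, ssb, e=0.0) -> np.ndarray | float:
    """Recruits produced at spawning biomass ``ssb`` (t) and environment ``e``.

    Vectorised over ``ssb`` and ``e``; returns 0 at SSB = 0 for every form.
    """
    s = np.asarray(ssb, dtype=float)
    if np.any(s < 0):
        raise InvalidArgumentError("ssb must be non-negative")
    e = np.asarray(e, dtype=float)
    alpha = np.exp(params.log_alpha)
    form = params.form
    if form in ("env_ricker", "ricker"):
        gamma = params.gamma if form == "env_ricker" else 0.0
        out = alpha * s * np.exp(-s * np.exp(-params.dd_log) - gamma * e)
    elif form in ("env_beverton_holt", "beverton_holt"):
        gamma = params.gamma if form == "env_beverton_holt" else 0.0
        out = np.exp(-gamma * e) * alpha * s / (1.0 + np.exp(params.dd_log) * s)
    else:  # hockey_stick
        out = alpha * np.minimum(s, params.break_ssb)
        out = out * np.ones_like(e)  # broadcast to e's shape for consistency
    if out.ndim == 0:
        return float(out)
    return out


def _log_predictions(form: str, theta: np.ndarray, s: np.ndarray,
                     e: np.ndarray) -> np.ndarray:
    """log R predicted by ``form`` at free-parameter vector ``theta``."""
    log_s = np.log(s)
    if form == "env_ricker":
        la, dd, g = theta
        return la + log_s - s * np.exp(-dd) - g * e
    if form == "ricker":
        la, dd = theta
        return la + log_s - s * np.exp(-dd)
    if form == "env_beverton_holt":
        la, dd, g = theta
        return la + log_s - np.log1p(np.exp(dd) * s) - g * e
    if form == "beverton_holt":
        la, dd = theta
        return la + log_s - np.log1p(np.exp(dd) * s)
    if form == "hockey_stick":
        la, dd = theta
        return la + np.log(np.minimum(s, np.exp(dd)))
    raise InvalidArgumentError(f"unknown SR form {form!r}")


def _start_values(form: str, s: np.ndarray, log_r: np.ndarray) -> np.ndarray:
    la0 = float(np.median(log_r - np.log(s)))
    log_s_med = float(np.log(np.median(s)))
    if form in ("env_ricker", "ricker"):
        dd0 = log_s_med  # density-dependence scale near typical SSB
    elif form in ("env_beverton_holt", "beverton_holt"):
        dd0 = -log_s_med  # beta ~ 1 / typical SSB
    else:
        dd0 = log_s_med
    theta = [la0 + 0.5, dd0]
    if form in ENV_FORMS:
        theta.append(0.5)
    return np.asarray(theta)


def fit_sr(series: ObservedSeries, form: str, n_restarts: int = 6,
           seed: int = 0, tol: float = 1e-10) -> FittedSR:
    """Fit one SR form to an observed series by lognormal maximum likelihood.

    Equivalent to least squares on log recruits over the log-parameterised
    free parameters. Multi-start Nelder-Mead polishing a BFGS solution
    guards against the non-convex hockey-stick objective. Standard errors
    are sigma_hat * sqrt(diag((J'J)^-1)) from the residual Jacobian at the
    optimum; AIC = 2k - 2 logL with the lognormal likelihood (k counts the
    free SR parameters plus the residual variance).
    """
    if form not in FORM_PARAMS:
        raise InvalidArgumentError(f"unknown SR form {form!r}")
    names = FORM_PARAMS[form]
    s = np.asarray(series.ssb, float)
    r = np.asarray(series.recruits, float)
    e = np.asarray(series.sst, float)
    if np.any(r <= 0):
        raise InvalidArgumentError("recruits must be strictly positive to fit")
    n = len(s)
    if n < len(names) + 2:
        raise InvalidArgumentError("series too short for this form")
    log_r = np.log(r)

    def rss(theta):
        resid = log_r - _log_predictions(form, theta, s, e)
        return float(resid @ resid)

    rng = np.random.default_rng(seed)
    theta0 = _start_values(form, s, log_r)
    best, diagnostics = None, []
    for i in range(n_restarts):
        start = theta0 if i == 0 else theta0 + rng.normal(0.0, 1.0, len(theta0))
        try:
            res = optimize.minimize(rss, start, method="Nelder-Mead",
                                    options={"xatol": 1e-9, "fatol": tol,
                                             "maxiter": 20_000})
            diagnostics.append({"start": start.tolist(), "fun": res.fun,
                                "success": bool(res.success)})
            if res.success and (best is None or res.fun < best.fun):
                best = res
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": start.tolist(), "error": str(exc)})
    if best is None:
        raise FitFailureError(f"no restart converged for form {form!r}",
                              diagnostics)

    theta = best.x
    resid = log_r - _log_predictions(form, theta, s, e)
    rss_min = float(resid @ resid)
    k_free = len(names)
    sigma2_mle = rss_min / n
    # lognormal log-likelihood (includes the Jacobian term -sum log R so
    # AICs are comparable across forms fitted to the same data)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0) - log_r.sum()
    aic = 2 * (k_free + 1) - 2 * loglik

    null_rss = float(np.sum((log_r - log_r.mean()) ** 2))
    deviance_explained = 1.0 - rss_min / null_rss if null_rss > 0 else 0.0

    # Gauss-Newton covariance: sigma_hat^2 * (J'J)^-1 with a 2-point Jacobian
    jac = np.empty((n, k_free))
    h = 1e-6
    for j in range(k_free):
        step = np.zeros(k_free)
        step[j] = h * max(1.0, abs(theta[j]))
        jac[:, j] = (_log_predictions(form, theta + step, s, e)
                     - _log_predictions(form, theta - step, s, e)) / (2 * step[j])
    dof = max(n - k_free, 1)
    sigma2_hat = rss_min / dof
    try:
        cov = sigma2_hat * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        raise FitFailureError(f"singular curvature for form {form!r}", diagnostics)
    # a noiseless (interpolating) fit has sigma_hat ~ 0; floor the SEs so
    # the FittedSR invariant (SE > 0) holds
    se = np.maximum(se, 1e-12)

    kwargs = dict(zip(names, theta))
    params = SRParams(form=form, **kwargs)
    return FittedSR(params=params,
                    standard_errors=dict(zip(names, se)),
                    aic=float(aic),
                    deviance_explained=float(deviance_explained),
                    n_obs=n)


def sampling_bounds(fitted: FittedSR) -> SamplingBounds:
    """Uniform sampling bounds: (estimate - SE, estimate + SE) per parameter."""
    est = {name: getattr(fitted.params, name)
           for name in FORM_PARAMS[fitted.params.form]}
    bounds = {name: (est[name] - se, est[name] + se)
              for name, se in fitted.standard_errors.items()}
    return SamplingBounds(form=fitted.params.form, bounds=bounds)


def compare_forms(series: ObservedSeries,
                  forms: Sequence[str] = ALL_FORMS,
                  seed: int = 0) -> pd.DataFrame:
    """Fit every candidate form and rank by AIC.

    Returns one row per (deduplicated) form with AIC, delta-AIC relative to
    the best form, and deviance explained; forms whose fit fails are kept
    as rows with the failure reason and missing statistics.
    """
    seen, rows = set(), []
    for form in forms:
        if form in seen:
            continue
        seen.add(form)
        try:
            fit = fit_sr(series, form, seed=seed)
            rows.append({"form": form, "aic": fit.aic,
                         "deviance_explained": fit.deviance_explained,
                         "failure": ""})
        except FitFailureError as exc:
            rows.append({"form": form, "aic": np.nan,
                         "deviance_explained": np.nan, "failure": str(exc)})
    df = pd.DataFrame(rows)
    best = df["aic"].min()
    df["delta_aic"] = df["aic"] - best
    return df.sort_values("aic").reset_index(drop=True)


def table1_midpoint_params(form: str) -> tuple[SRParams, SamplingBounds]:
    """Midpoints and half-widths of the published uniform sampling bounds.

    These are the generating values used throughout the synthetic study:
    Ricker log_alpha in [8.67, 12.02], dd_log in [11.90, 12.64], gamma in
    [0.64, 0.95]; Beverton-Holt log_alpha in [9.35, 13.23], dd_log in
    [-11.96, -10.36], gamma in [0.69, 1.01].
    """
    table = {
        "env_ricker": {"log_alpha": (8.67, 12.02), "dd_log": (11.90, 12.64),
                       "gamma": (0.64, 0.95)},
        "env_beverton_holt": {"log_alpha": (9.35, 13.23),
                              "dd_log": (-11.96, -10.36),
                              "gamma": (0.69, 1.01)},
    }
    if form not in table:
        raise InvalidArgumentError(f"no published bounds for form {form!r}")
    bounds = table[form]
    mid = {k: 0.5 * (lo + hi) for k, (lo, hi) in bounds.items()}
    return (SRParams(form=form, **mid),
            SamplingBounds(form=form, bounds=bounds))


def write_bounds(all_bounds: Sequence[SamplingBounds], path) -> None:
    rows = [{"model": b.form, "parameter": name, "lower": lo, "upper": hi}
            for b in all_bounds for name, (lo, hi) in b.bounds.items()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_bounds(path) -> dict[str, SamplingBounds]:
    df = pd.read_csv(path)
    out = {}
    for form, grp in df.groupby("model"):
        out[str(form)] = SamplingBounds(
            form=str(form),
            bounds={row["parameter"]: (row["lower"], row["upper"])
                    for _, row in grp.iterrows()})
    return out
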