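"""Candidate growth curves for biomass-age data and AIC model selection.

Four commonly used growth functions for aboveground biomass y as a function
of stand age x, all constrained through the origin (a stand of age zero has
no biomass):

- linear:            f(x) = beta * x
- exponential:       f(x) = beta * log(x + 1)
- chapman_richards:  f(x) = mu * (1 - exp(-k * x))
- monod:             f(x) = mu * x / (k + x)

The two saturating forms share the interpretation of ``mu`` as the asymptotic
saturated biomass; for the Monod (Michaelis-Menten) curve ``k`` is the stand
age at which biomass reaches mu/2.

Each model is fitted by maximum likelihood under i.i.d. additive normal
errors: the curve parameters by (closed-form or multi-start bounded
nonlinear) least squares, sigma by the ML estimator RMSE = sqrt(SSR/n).
Models are compared by AIC = 2p - 2 logL with p counting sigma as a free
parameter; lower is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MODELS",
    "SATURATING_MODELS",
    "GrowthFitResult",
    "eval_growth",
    "fit_growth",
    "fit_growth_xy",
    "aic_rank",
    "select_by_type",
]

MODELS = ("linear", "exponential", "chapman_richards", "monod")
SATURATING_MODELS = ("chapman_richards", "monod")

#: Floor on the ML residual SD so a perfect fit keeps the log-likelihood finite.
SIGMA_FLOOR = 1e-8

_N_CURVE_PARAMS = {"linear": 1, "exponential": 1, "chapman_richards": 2, "monod": 2}


@dataclass
class GrowthFitResult:
    """One growth-model fit on one dataset."""

    model: str
    params: dict[str, float]
    sigma: float
    loglik: float
    aic: float
    n: int
    converged: bool = True
    sigma_floored: bool = field(default=False, repr=False)

    @property
    def n_params(self) -> int:
        """Free parameters including sigma."""
        return _N_CURVE_PARAMS[self.model] + 1


def eval_growth(model: str, params: dict[str, float], x) -> np.ndarray:
    """Evaluate a growth curve at ages ``x`` (years); f(0) = 0 for all models."""
    x = np.asarray(x, dtype=float)
    if model == "linear":
        return params["beta"] * x
    if model == "exponential":
        return params["beta"] * np.log1p(x)
    if model in SATURATING_MODELS:
        mu, k = params["mu"], params["k"]
        if k <= 0:
            raise ValueError(f"{model} requires k > 0, got {k}")
        if model == "chapman_richards":
            return mu * (1.0 - np.exp(-k * x))
        return mu * x / (k + x)
    raise ValueError(f"unknown growth model {model!r}")


def _normal_loglik(ssr: float, n: int) -> tuple[float, float, bool]:
    """(loglik, sigma, floored) under ML-normal errors with sigma^2 = SSR/n."""
    sigma2 = ssr / n
    floored = sigma2 < SIGMA_FLOOR**2
    sigma2 = max(sigma2, SIGMA_FLOOR**2)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + ssr / (n * sigma2))
    return float(ll), float(np.sqrt(sigma2)), floored


def fit_growth_xy(x, y, model: str) -> GrowthFitResult:
    """Fit one growth model to ages ``x`` and biomass ``y`` by ML.

    Linear and exponential models are solved in closed form (least squares on
    the transformed regressor). The saturating models use bounded nonlinear
    least squares with a multi-start grid over (mu, k), because Monod-type
    fits are ill-conditioned when the data do not reach saturation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    p = _N_CURVE_PARAMS[model] + 1
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} plots to fit {model}, got {n}")
    if np.any(x <= 0):
        raise ValueError("stand ages must be positive")

    converged = True
    if model in ("linear", "exponential"):
        g = x if model == "linear" else np.log1p(x)
        beta = float(g @ y / (g @ g))
        resid = y - beta * g
        params = {"beta": beta}
        ssr = float(resid @ resid)
    else:
        mu_starts = np.array([0.5, 1.0, 2.0]) * max(float(np.max(y)), 1.0)
        k_med = max(float(np.median(x)), 1.0)
        k_starts = np.array([0.25, 1.0, 4.0]) * k_med
        if model == "chapman_richards":
            # rate parameter: half-saturation age a maps to k = log(2)/a
            k_starts = np.log(2.0) / k_starts

        def resid_fn(theta):
            return eval_growth(model, {"mu": theta[0], "k": theta[1]}, x) - y

        best = None
        any_success = False
        for mu0 in mu_starts:
            for k0 in k_starts:
                sol = least_squares(
                    resid_fn,
                    x0=[mu0, k0],
                    bounds=([1e-8, 1e-12], [np.inf, np.inf]),
                    method="trf",
                )
                any_success = any_success or sol.success
                cost = 2.0 * sol.cost
                if best is None or cost < best[0]:
                    best = (cost, sol.x)
        ssr, theta = best
        converged = bool(any_success)
        params = {"mu": float(theta[0]), "k": float(theta[1])}

    ll, sigma, floored = _normal_loglik(ssr, n)
    aic = 2.0 * p - 2.0 * ll
    return GrowthFitResult(
        model=model,
        params=params,
        sigma=sigma,
        loglik=ll,
        aic=aic,
        n=n,
        converged=converged,
        sigma_floored=floored,
    )


def fit_growth(plots: pd.DataFrame, model: str) -> GrowthFitResult:
    """Fit one growth model to a plot table (columns stand_age, agb)."""
    return fit_growth_xy(plots["stand_age"].to_numpy(), plots["agb"].to_numpy(), model)


def aic_rank(fits: list[GrowthFitResult]) -> list[str]:
    """Model names in order of AIC preference (ascending AIC).

    Fits whose AIC is within 2 of the group's running best are treated as
    ties and broken toward fewer parameters, then toward the Monod model
    (preferred in this analysis for its interpretable parameters).
    """
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits compare different sample sizes: {sorted(ns)}")
    by_aic = sorted(fits, key=lambda f: f.aic)
    groups: list[list[GrowthFitResult]] = []
    for f in by_aic:
        if groups and f.aic - groups[-1][0].aic < 2.0:
            groups[-1].append(f)
        else:
            groups.append([f])
    ordered: list[str] = []
    for grp in groups:
        grp.sort(key=lambda f: (f.n_params, f.model != "monod", f.aic))
        ordered.extend(f.model for f in grp)
    return ordered


def select_by_type(plots: pd.DataFrame) -> pd.DataFrame:
    """Fit all four growth models per forest type and rank them by AIC.

    Returns one row per (forest_type, model) with the fitted parameters,
    log-likelihood, AIC, and rank (1 = preferred).
    """
    rows = []
    for ftype, sub in plots.groupby("forest_type", sort=True):
        fits = [fit_growth(sub, m) for m in MODELS]
        order = aic_rank(fits)
        rank = {m: i + 1 for i, m in enumerate(order)}
        for f in fits:
            rows.append(
                {
                    "forest_type": ftype,
                    "model": f.model,
                    "beta": f.params.get("beta", np.nan),
                    "mu": f.params.get("mu", np.nan),
                    "k": f.params.get("k", np.nan),
                    "sigma": f.sigma,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "rank": rank[f.model],
                    "n": f.n,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)
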