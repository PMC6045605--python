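"""Hindcast, forecast, and saturation-ratio computation.

Hindcast and forecast are the same operator — the noise-free Monod mean

    y_hat = mu_hat * age / (k_hat + age)

with mu_hat, k_hat linear in climate centered on the CURRENT-period
per-type means — applied to different inputs: past covariates and observed
past ages for the hindcast, projected climate and forward-extrapolated
ages for the forecast. No error term is added; predictions carry parameter
uncertainty only.

Two prediction paths are exposed. The point path plugs in posterior-mean
parameters (the convention of the original analysis and the default for
the saturation ratio). The posterior path propagates every retained draw
and reports the mean and the 2.5%/97.5% quantiles of the resulting
parameter-uncertainty distribution.

The saturation ratio current / future quantifies how close present biomass
stands to its best-case future potential (no further disturbance): values
near 1 mean little remaining growth potential. Ratios can exceed 1 when
observed biomass sits above the modelled potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbmodel import ForestTypeParams, PosteriorDraws, mu_k_of_climate

__all__ = [
    "PERIOD_MIDPOINTS",
    "Prediction",
    "RatioResult",
    "predict_mean",
    "point_predict",
    "posterior_predict",
    "extrapolate_age",
    "hindcast",
    "forecast",
    "saturation_ratio",
]

#: Calendar midpoint of each future period, used for age extrapolation.
PERIOD_MIDPOINTS = {"2020s": 2025, "2050s": 2055, "2080s": 2085}

PREDICTION_COLUMNS = ["plot_id", "kind", "mean", "cri_lo", "cri_hi", "scenario", "period"]


@dataclass(frozen=True)
class Prediction:
    """One plot's noise-free biomass prediction with credible bounds."""

    plot_id: str
    kind: str
    mean: float
    cri_lo: float
    cri_hi: float
    scenario: str | None = None
    period: str | None = None


@dataclass
class RatioResult:
    """Cohort summary of per-plot current/future biomass ratios."""

    per_plot: pd.DataFrame
    mean: float
    sd: float
    quantiles: dict[str, float]
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list, repr=False)


def predict_mean(params: ForestTypeParams, mat, map, age) -> np.ndarray:
    """Noise-free Monod mean biomass at given climate and age (vectorized).

    Raises if any denominator k_hat + age is nonpositive (prediction
    undefined there); negative predicted means are floored at zero, since
    biomass is physical.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    mu, k = mu_k_of_climate(params, mat, map)
    denom = k + age
    if np.any(denom <= 0):
        raise ValueError("nonpositive Monod denominator k + age at prediction point")
    return np.maximum(mu * age / denom, 0.0)


def _prediction_frame(plots, kind, mean, lo, hi, scenario, period) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy(),
            "kind": kind,
            "mean": mean,
            "cri_lo": lo,
            "cri_hi": hi,
            "scenario": scenario,
            "period": period,
        }
    )[PREDICTION_COLUMNS]


def point_predict(
    plots: pd.DataFrame,
    params: dict[str, ForestTypeParams] | ForestTypeParams,
    mat=None, map=None, ages=None, kind: str = "in_sample",
    scenario: str | None = None, period: str | None = None,
) -> pd.DataFrame:
    """Point-estimate predictions (credible bounds collapse onto the mean)."""
    mat = plots["mat"].to_numpy() if mat is None else np.asarray(mat, dtype=float)
    map_ = plots["map"].to_numpy() if map is None else np.asarray(map, dtype=float)
    ages = plots["stand_age"].to_numpy() if ages is None else np.asarray(ages, dtype=float)
    mean = np.empty(len(plots))
    for ftype, idx in _groups(plots, params):
        p = params[ftype] if isinstance(params, dict) else params
        mean[idx] = predict_mean(p, mat[idx], map_[idx], ages[idx])
    return _prediction_frame(plots, kind, mean, mean, mean, scenario, period)


def _groups(plots: pd.DataFrame, params):
    keys = plots["forest_type"].to_numpy()
    if isinstance(params, dict):
        missing = sorted(set(keys) - set(params))
        if missing:
            raise KeyError(f"no fitted parameters for forest type(s): {', '.join(missing)}")
        for ftype in np.unique(keys):
            yield str(ftype), np.flatnonzero(keys == ftype)
    else:
        yield str(keys[0]) if len(keys) else "", np.arange(len(plots))


def _draw_matrix(draws: PosteriorDraws, max_draws: int) -> np.ndarray:
    pooled = draws.pooled()
    if pooled.shape[0] > max_draws:
        # deterministic even thinning keeps predictions reproducible
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).round().astype(int)
        pooled = pooled[idx]
    return pooled


def posterior_predict(
    plots: pd.DataFrame,
    draws: dict[str, PosteriorDraws] | PosteriorDraws,
    mat=None, map=None, ages=None, kind: str = "in_sample",
    scenario: str | None = None, period: str | None = None,
    max_draws: int = 2000,
) -> pd.DataFrame:
    """Per-plot posterior-mean prediction and central 95% credible interval.

    The Monod mean is evaluated at every retained draw (evenly thinned to at
    most ``max_draws``); draws giving a nonpositive denominator for a plot
    are excluded from that plot's distribution, and negative means floored
    at zero. Parameter uncertainty only — no residual noise is added.
    """
    mat = plots["mat"].to_numpy() if mat is None else np.asarray(mat, dtype=float)
    map_ = plots["map"].to_numpy() if map is None else np.asarray(map, dtype=float)
    ages = plots["stand_age"].to_numpy() if ages is None else np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")

    mean = np.empty(len(plots))
    lo = np.empty(len(plots))
    hi = np.empty(len(plots))
    if isinstance(draws, PosteriorDraws):
        draws = {draws.forest_type: draws}
    for ftype, idx in _groups(plots, draws):
        d = draws[ftype]
        mat_c = mat[idx] - d.t_bar
        map_c = map_[idx] - d.p_bar
        age = ages[idx]
        dm = _draw_matrix(d, max_draws)  # (ndraw, 7)
        mu = dm[:, [0]] + dm[:, [1]] * mat_c + dm[:, [2]] * map_c
        k = dm[:, [3]] + dm[:, [4]] * mat_c + dm[:, [5]] * map_c
        denom = k + age
        with np.errstate(divide="ignore", invalid="ignore"):
            pred = np.where(denom > 0, np.maximum(mu * age / denom, 0.0), np.nan)
        mean[idx] = np.nanmean(pred, axis=0)
        lo[idx] = np.nanquantile(pred, 0.025, axis=0)
        hi[idx] = np.nanquantile(pred, 0.975, axis=0)
    return _prediction_frame(plots, kind, mean, lo, hi, scenario, period)


def extrapolate_age(stand_age, obs_year, period: str, midpoints=None):
    """Forward-extrapolated stand age at a future period's midpoint.

    Assumes undisturbed growth: a stand aged ``a`` when observed in year
    ``t`` is aged ``a + (midpoint - t)`` at the period midpoint.
    """
    midpoints = midpoints or PERIOD_MIDPOINTS
    if period not in midpoints:
        raise KeyError(f"unknown future period {period!r}")
    return np.asarray(stand_age, dtype=float) + (midpoints[period] - np.asarray(obs_year))


def hindcast(
    past_plots: pd.DataFrame,
    fit: dict[str, PosteriorDraws] | dict[str, ForestTypeParams],
    method: str = "point",
    max_draws: int = 2000,
) -> pd.DataFrame:
    """Out-of-sample prediction of past-period biomass from the current fit.

    Uses past stand ages and past climate but the CURRENT-period climate
    centers stored on the fit (the space-for-time validation design).
    """
    return _predict(past_plots, fit, method, kind="hindcast", max_draws=max_draws)


def _predict(plots, fit, method, kind, mat=None, map=None, ages=None,
             scenario=None, period=None, max_draws=2000):
    if method == "point":
        params = {
            ft: (d.posterior_mean_params() if isinstance(d, PosteriorDraws) else d)
            for ft, d in fit.items()
        }
        return point_predict(plots, params, mat, map, ages, kind, scenario, period)
    if method == "posterior":
        if not all(isinstance(d, PosteriorDraws) for d in fit.values()):
            raise TypeError("posterior method requires PosteriorDraws per type")
        return posterior_predict(
            plots, fit, mat, map, ages, kind, scenario, period, max_draws
        )
    raise ValueError(f"unknown prediction method {method!r}")


def forecast(
    plots: pd.DataFrame,
    fit: dict[str, PosteriorDraws] | dict[str, ForestTypeParams],
    scenario_climate: pd.DataFrame,
    scenario: str,
    period: str,
    method: str = "point",
    midpoints=None,
    max_draws: int = 2000,
) -> pd.DataFrame:
    """Best-case future biomass under a projected climate scenario.

    Climate covariates come from the scenario table (still centered on the
    current-period means); stand ages are extrapolated to the period
    midpoint; no disturbance is assumed.
    """
    scen = scenario_climate.loc[
        (scenario_climate["scenario"] == scenario)
        & (scenario_climate["period"] == period)
    ]
    merged = plots.merge(scen[["plot_id", "mat_proj", "map_proj"]], on="plot_id", how="left")
    if merged["mat_proj"].isna().any():
        missing = merged.loc[merged["mat_proj"].isna(), "plot_id"].head(5).tolist()
        raise ValueError(
            f"scenario climate missing for {int(merged['mat_proj'].isna().sum())} "
            f"plot(s) under {scenario}/{period}, e.g. {missing}"
        )
    ages = extrapolate_age(
        merged["stand_age"].to_numpy(), merged["obs_year"].to_numpy(), period, midpoints
    )
    return _predict(
        merged, fit, method, kind="forecast",
        mat=merged["mat_proj"].to_numpy(), map=merged["map_proj"].to_numpy(),
        ages=ages, scenario=scenario, period=period, max_draws=max_draws,
    )


def saturation_ratio(current, future: pd.DataFrame) -> RatioResult:
    """Per-plot current/future biomass ratio and its cohort summary.

    ``current`` is either a prediction table (modelled current biomass) or a
    plot table (observed biomass, the default convention). Plots whose
    future mean is nonpositive are excluded and reported. Summaries are the
    cohort mean +/- SD plus the 5/25/50/75/95% quantiles.
    """
    if "mean" in current.columns:
        cur = current[["plot_id", "mean"]].rename(columns={"mean": "current"})
    elif "agb" in current.columns:
        cur = current[["plot_id", "agb"]].rename(columns={"agb": "current"})
    else:
        raise ValueError("current table must carry 'mean' (predicted) or 'agb' (observed)")
    fut = future[["plot_id", "mean"]].rename(columns={"mean": "future"})
    merged = cur.merge(fut, on="plot_id", how="inner")
    bad = merged["future"] <= 0
    excluded = merged.loc[bad, "plot_id"].tolist()
    ok = merged.loc[~bad].copy()
    ok["ratio"] = ok["current"] / ok["future"]
    r = ok["ratio"].to_numpy()
    qs = np.quantile(r, [0.05, 0.25, 0.5, 0.75, 0.95]) if r.size else [np.nan] * 5
    return RatioResult(
        per_plot=ok[["plot_id", "current", "future", "ratio"]],
        mean=float(np.mean(r)) if r.size else np.nan,
        sd=float(np.std(r, ddof=1)) if r.size > 1 else np.nan,
        quantiles={k: float(v) for k, v in zip(["q5", "q25", "q50", "q75", "q95"], qs)},
        n_excluded=len(excluded),
        excluded_ids=excluded,
    )
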