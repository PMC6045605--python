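"""Grid aggregation, the spatially modified t-test, and cross-validation.

Observed and predicted biomass are compared after averaging onto a
10-arcmin (1/6 degree) longitude x latitude grid, the resolution at which
continental biomass maps are usually summarized. Because neighbouring grid
cells are spatially autocorrelated, the significance of the
observed-vs-predicted Pearson correlation is assessed with a modified
t-test in the Clifford-Richardson-Hemon / Dutilleul tradition: the
effective sample size is deflated according to the spatial autocorrelation
of both fields, estimated on great-circle distance classes, and the t
reference distribution uses the deflated degrees of freedom.

Cross-validation follows the 75/25 convention: a random plot-level split,
model fitted on the training plots, predictions on the held-out plots,
and agreement summarized on the grid with the modified t-test (the split
itself is random; the evaluation is what is spatial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hbmodel import PosteriorDraws, fit_all_types
from .projection import point_predict, posterior_predict

__all__ = [
    "EARTH_RADIUS_KM",
    "GridCell",
    "ModifiedTTestResult",
    "CVResult",
    "great_circle_km",
    "grid_average",
    "modified_ttest",
    "spatial_cv",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridCell:
    """One 10-arcmin grid cell with averaged values."""

    lon_idx: int
    lat_idx: int
    lon_center: float
    lat_center: float
    mean_obs: float
    mean_pred: float
    n_plots: int


@dataclass
class ModifiedTTestResult:
    """Correlation between two gridded fields with spatial correction."""

    r: float
    n_cells: int
    effective_n: float
    t_stat: float
    p_value: float


@dataclass
class CVResult:
    """75/25 cross-validation outcome."""

    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)
    fits: dict[str, PosteriorDraws] = field(repr=False)
    grid: pd.DataFrame = field(repr=False)
    ttest: ModifiedTTestResult = None
    excluded_types: list[str] = field(default_factory=list)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (spherical law of cosines)."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    cosang = (
        np.sin(phi1) * np.sin(phi2)
        + np.cos(phi1) * np.cos(phi2) * np.cos(lam2 - lam1)
    )
    return EARTH_RADIUS_KM * np.arccos(np.clip(cosang, -1.0, 1.0))


def grid_average(
    plots: pd.DataFrame,
    values: dict[str, np.ndarray] | None = None,
    resolution_arcmin: float = 10.0,
) -> pd.DataFrame:
    """Average per-plot values onto a regular lon/lat grid.

    Cells are half-open intervals [i*w, (i+1)*w) with w = resolution in
    degrees, so a plot exactly on a boundary joins the higher-index cell.
    ``values`` maps output column names to per-plot arrays; by default the
    plot table's observed biomass is averaged as ``mean_obs``. The summed
    ``n_plots`` over cells equals the number of input plots.
    """
    if values is None:
        values = {"mean_obs": plots["agb"].to_numpy()}
    w = resolution_arcmin / 60.0
    lon = plots["lon"].to_numpy(dtype=float)
    lat = plots["lat"].to_numpy(dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("non-finite coordinates")
    tmp = pd.DataFrame(
        {"lon_idx": np.floor(lon / w).astype(int), "lat_idx": np.floor(lat / w).astype(int)}
    )
    for name, arr in values.items():
        tmp[name] = np.asarray(arr, dtype=float)
    agg = {name: (name, "mean") for name in values}
    agg["n_plots"] = ("lon_idx", "size")
    out = tmp.groupby(["lon_idx", "lat_idx"], sort=True).agg(**agg).reset_index()
    out.insert(2, "lon_center", (out["lon_idx"] + 0.5) * w)
    out.insert(3, "lat_center", (out["lat_idx"] + 0.5) * w)
    return out


def _correlogram_matrix(z: np.ndarray, classes: np.ndarray, n_classes: int) -> np.ndarray:
    """Estimated spatial correlation matrix from a distance-class correlogram.

    ``z`` must be standardized; the autocorrelation of each distance class
    is the mean cross-product over cell pairs in the class.
    """
    n = z.size
    rho = np.ones(n_classes)
    prod = np.outer(z, z)
    iu = np.triu_indices(n, k=1)
    cls_u = classes[iu]
    prod_u = prod[iu]
    for c in range(n_classes):
        mask = cls_u == c
        if mask.any():
            rho[c] = np.clip(prod_u[mask].mean(), -1.0, 1.0)
        else:
            rho[c] = 0.0
    mat = rho[classes]
    np.fill_diagonal(mat, 1.0)
    return mat


def modified_ttest(
    a, b, lon, lat, n_classes: int = 10
) -> ModifiedTTestResult:
    """Correlation of two spatial fields with autocorrelation-corrected df.

    Pearson r is computed on the cell values. The effective sample size
    follows Dutilleul's estimator: with C the centering matrix and
    Sigma_a, Sigma_b the correlation matrices implied by each field's
    distance-class correlogram,

        M = 1 + tr(C Sigma_a C) tr(C Sigma_b C) / tr(C Sigma_a C Sigma_b C)

    which reduces to n for spatially independent fields. The t statistic
    r * sqrt((M - 2) / (1 - r^2)) is referred to a t distribution with
    M - 2 degrees of freedom (two-sided).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = a.size
    if n < 10:
        raise ValueError(f"need >= 10 common cells, got {n}")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance in one of the fields")

    r = float(np.corrcoef(a, b)[0, 1])

    dist = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    iu = np.triu_indices(n, k=1)
    # equal-count distance classes from the pairwise distance distribution
    edges = np.quantile(dist[iu], np.linspace(0.0, 1.0, n_classes + 1)[1:])
    classes = np.searchsorted(edges, dist, side="left")
    classes = np.minimum(classes, n_classes - 1)

    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    sig_a = _correlogram_matrix(za, classes, n_classes)
    sig_b = _correlogram_matrix(zb, classes, n_classes)

    C = np.eye(n) - np.full((n, n), 1.0 / n)
    ca = C @ sig_a @ C
    cb = C @ sig_b @ C
    denom = float(np.trace(ca @ cb))
    if denom <= 0:
        eff_n = float(n)
    else:
        eff_n = 1.0 + float(np.trace(ca)) * float(np.trace(cb)) / denom
    eff_n = min(eff_n, float(n))

    if eff_n <= 2.0:
        return ModifiedTTestResult(r, n, eff_n, np.nan, 1.0)
    t = r * np.sqrt((eff_n - 2.0) / max(1.0 - r * r, 1e-15))
    p = 2.0 * stats.t.sf(abs(t), df=eff_n - 2.0)
    return ModifiedTTestResult(r, n, float(eff_n), float(t), float(p))


def spatial_cv(
    plots: pd.DataFrame,
    train_frac: float = 0.75,
    seed: int = 0,
    method: str = "point",
    resolution_arcmin: float = 10.0,
    min_train_per_type: int = 8,
    **mcmc_kw,
) -> CVResult:
    """Random 75/25 plot-level split with spatially corrected evaluation.

    The model is fitted per forest type on the training plots (current
    period), held-out plots are predicted, both observed and predicted
    biomass are averaged on the grid, and agreement is summarized with the
    modified t-test. Test plots whose type is absent (or too thin) in the
    training split are excluded and reported.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(plots)
    rng = np.random.default_rng([seed, 17])
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = plots.iloc[train_idx]
    test = plots.iloc[test_idx]

    counts = train["forest_type"].value_counts()
    fit_types = set(counts[counts >= min_train_per_type].index)
    excluded = sorted(set(test["forest_type"]) - fit_types)
    train = train.loc[train["forest_type"].isin(fit_types)]
    test = test.loc[test["forest_type"].isin(fit_types)].copy()

    fits = fit_all_types(train, seed=seed, **mcmc_kw)
    if method == "point":
        params = {ft: d.posterior_mean_params() for ft, d in fits.items()}
        pred = point_predict(test, params, kind="in_sample")
    else:
        pred = posterior_predict(test, fits, kind="in_sample")

    grid = grid_average(
        test,
        values={
            "mean_obs": test["agb"].to_numpy(),
            "mean_pred": pred["mean"].to_numpy(),
        },
        resolution_arcmin=resolution_arcmin,
    )
    tt = modified_ttest(
        grid["mean_obs"], grid["mean_pred"], grid["lon_center"], grid["lat_center"]
    )
    return CVResult(
        train_idx=train_idx, test_idx=test_idx, fits=fits, grid=grid,
        ttest=tt, excluded_types=excluded,
    )
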