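"""Per-forest-type Bayesian Monod growth model with climate-dependent parameters.

For plot i in forest type j the aboveground biomass follows

    y_ij = mu_ij * x_ij / (k_ij + x_ij) + eps_ij,   eps_ij ~ N(0, sigma_j^2)

where x_ij is stand age and the Monod parameters are linear in centered
climate covariates (T = mean annual temperature, P = mean annual
precipitation):

    mu_ij = beta0_j + beta1_j (T_ij - Tbar_j) + beta2_j (P_ij - Pbar_j)
    k_ij  = gamma0_j + gamma1_j (T_ij - Tbar_j) + gamma2_j (P_ij - Pbar_j)

so beta0_j is the asymptotic saturated biomass on an average climate and
gamma0_j the half-saturation age on an average climate; the slopes quantify
climate modification of the recovery trajectory. Each forest type is fitted
separately (no cross-type hyperpriors).

Priors are noninformative: U(-1e5, 1e5) on the six regression parameters
(optionally truncated to beta0, gamma0 > 0) and inverse-gamma
IG(shape=1e-5, rate=1e-5) on sigma_j^2. Posteriors are simulated with an
adaptive random-walk Metropolis-within-Gibbs sampler: one scalar
random-walk block per regression parameter (proposal SDs tuned during
burn-in toward ~0.3 acceptance) and an exact conjugate inverse-gamma Gibbs
draw for sigma_j^2. Parameter points that would make any Monod denominator
k_ij + x_ij nonpositive over the observed plots receive log-likelihood
-inf and are always rejected.

Convergence is assessed with Geweke z-scores (early vs. late segment means
with spectral-density-at-zero variance estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import fit_growth_xy
from .inventory import climate_centers

__all__ = [
    "PARAM_NAMES",
    "ForestTypeParams",
    "PriorSpec",
    "PosteriorDraws",
    "mu_k_of_climate",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "run_mcmc",
    "fit_forest_type",
    "fit_all_types",
    "geweke_z",
    "geweke_table",
    "summarize_posterior",
]

#: Parameter order used throughout draws arrays and summaries.
PARAM_NAMES = ("beta0", "beta1", "beta2", "gamma0", "gamma1", "gamma2", "sigma2")


@dataclass
class ForestTypeParams:
    """The seven model parameters of one forest type plus its climate centers.

    Units: beta0 Mg/ha; beta1 Mg/ha/degC; beta2 Mg/ha/mm; gamma0 yr;
    gamma1 yr/degC; gamma2 yr/mm; sigma2 (Mg/ha)^2; t_bar degC; p_bar mm.
    """

    forest_type: str
    beta0: float
    beta1: float
    beta2: float
    gamma0: float
    gamma1: float
    gamma2: float
    sigma2: float
    t_bar: float
    p_bar: float

    def theta(self) -> np.ndarray:
        """The six regression parameters as an array (no sigma2)."""
        return np.array(
            [self.beta0, self.beta1, self.beta2, self.gamma0, self.gamma1, self.gamma2]
        )

    @classmethod
    def from_theta(
        cls, forest_type: str, theta, sigma2: float, t_bar: float, p_bar: float
    ) -> "ForestTypeParams":
        b0, b1, b2, g0, g1, g2 = (float(v) for v in theta)
        return cls(forest_type, b0, b1, b2, g0, g1, g2, float(sigma2), t_bar, p_bar)


@dataclass(frozen=True)
class PriorSpec:
    """Noninformative prior configuration.

    ``flat`` puts U(-bound, bound) on all six regression parameters;
    ``positive_truncated`` additionally restricts beta0 and gamma0 to
    (0, bound), encoding positive saturated biomass and half-saturation age
    on an average climate. sigma2 gets IG(ig_shape, ig_rate) (shape/rate
    parametrization) under both variants.
    """

    variant: str = "flat"
    bound: float = 1e5
    ig_shape: float = 1e-5
    ig_rate: float = 1e-5

    def __post_init__(self):
        if self.variant not in ("flat", "positive_truncated"):
            raise ValueError(f"unknown prior variant {self.variant!r}")
        if self.bound <= 0 or self.ig_shape <= 0 or self.ig_rate <= 0:
            raise ValueError("bound, ig_shape, ig_rate must all be > 0")


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC samples for one forest type.

    ``draws`` has shape (chains, iterations_kept, 7) with the parameter order
    of :data:`PARAM_NAMES`.
    """

    forest_type: str
    draws: np.ndarray
    burn_in: int
    seed: int
    t_bar: float
    p_bar: float
    acceptance: np.ndarray | None = field(default=None, repr=False)

    @property
    def chains(self) -> int:
        return self.draws.shape[0]

    @property
    def kept(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains concatenated, shape (chains * kept, 7)."""
        return self.draws.reshape(-1, len(PARAM_NAMES))

    def posterior_mean_params(self) -> ForestTypeParams:
        m = self.pooled().mean(axis=0)
        return ForestTypeParams.from_theta(
            self.forest_type, m[:6], m[6], self.t_bar, self.p_bar
        )

    def to_frame(self) -> pd.DataFrame:
        ch, it, _ = self.draws.shape
        df = pd.DataFrame(self.pooled(), columns=list(PARAM_NAMES))
        df.insert(0, "iter", np.tile(np.arange(it), ch))
        df.insert(0, "chain", np.repeat(np.arange(ch), it))
        return df

    @classmethod
    def from_frame(
        cls, forest_type: str, df: pd.DataFrame, burn_in: int, seed: int,
        t_bar: float, p_bar: float,
    ) -> "PosteriorDraws":
        ch = int(df["chain"].max()) + 1
        it = int(df["iter"].max()) + 1
        arr = df[list(PARAM_NAMES)].to_numpy().reshape(ch, it, len(PARAM_NAMES))
        return cls(forest_type, arr, burn_in, seed, t_bar, p_bar)


def mu_k_of_climate(params: ForestTypeParams, mat, map) -> tuple[np.ndarray, np.ndarray]:
    """Monod asymptote mu (Mg/ha) and half-saturation age k (yr) at a climate.

    Exact linear forms in the centered covariates; negative values are not
    clipped here (they are handled by the likelihood support rule and by the
    prediction layer).
    """
    dT = np.asarray(mat, dtype=float) - params.t_bar
    dP = np.asarray(map, dtype=float) - params.p_bar
    mu = params.beta0 + params.beta1 * dT + params.beta2 * dP
    k = params.gamma0 + params.gamma1 * dT + params.gamma2 * dP
    return mu, k


def _design(plots: pd.DataFrame, t_bar: float, p_bar: float):
    x = plots["stand_age"].to_numpy(dtype=float)
    y = plots["agb"].to_numpy(dtype=float)
    dT = plots["mat"].to_numpy(dtype=float) - t_bar
    dP = plots["map"].to_numpy(dtype=float) - p_bar
    return x, y, dT, dP


def _ssr(theta: np.ndarray, x, y, dT, dP) -> float:
    """Residual sum of squares at theta; inf if any denominator k+x <= 0."""
    k = theta[3] + theta[4] * dT + theta[5] * dP
    denom = k + x
    if denom.min() <= 0.0:
        return np.inf
    mu = theta[0] + theta[1] * dT + theta[2] * dP
    r = y - mu * x / denom
    return float(r @ r)


def log_likelihood(plots: pd.DataFrame, params: ForestTypeParams) -> float:
    """Normal log-likelihood of a single-type plot table at ``params``.

    Returns ``-inf`` when any plot has k_ij + x_ij <= 0 (the Monod mean is
    undefined or non-physical there).
    """
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x, y, dT, dP = _design(plots, params.t_bar, params.p_bar)
    if np.any(x <= 0):
        raise ValueError("stand ages must be positive")
    ssr = _ssr(params.theta(), x, y, dT, dP)
    if not np.isfinite(ssr):
        return -np.inf
    n = x.size
    return float(-0.5 * n * np.log(2.0 * np.pi * params.sigma2) - ssr / (2.0 * params.sigma2))


def log_prior(params: ForestTypeParams, prior: PriorSpec) -> float:
    """Log prior density (unnormalized only through the uniform constants)."""
    theta = params.theta()
    if np.any(np.abs(theta) >= prior.bound):
        return -np.inf
    if prior.variant == "positive_truncated" and (params.beta0 <= 0 or params.gamma0 <= 0):
        return -np.inf
    n_pos = 2 if prior.variant == "positive_truncated" else 0
    lp = -(6 - n_pos) * np.log(2.0 * prior.bound) - n_pos * np.log(prior.bound)
    if params.sigma2 <= 0:
        return -np.inf
    lp += stats.invgamma.logpdf(params.sigma2, prior.ig_shape, scale=prior.ig_rate)
    return float(lp)


def log_posterior(plots: pd.DataFrame, params: ForestTypeParams, prior: PriorSpec) -> float:
    """log posterior = log likelihood + log prior (up to a constant)."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(plots, params) + lp


def _in_support(theta: np.ndarray, prior: PriorSpec) -> bool:
    if np.any(np.abs(theta) >= prior.bound):
        return False
    if prior.variant == "positive_truncated" and (theta[0] <= 0 or theta[3] <= 0):
        return False
    return True


def _init_theta(x, y) -> np.ndarray:
    """Starting point from a climate-free Monod least-squares fit."""
    fit = fit_growth_xy(x, y, "monod")
    return np.array([fit.params["mu"], 0.0, 0.0, fit.params["k"], 0.0, 0.0])


def _run_chain(
    x, y, dT, dP, prior: PriorSpec, iterations: int, burn_in: int,
    rng: np.random.Generator, theta0: np.ndarray, prop_sd0: np.ndarray,
    target_accept: float = 0.3, adapt_window: int = 50,
):
    n = x.size
    theta = theta0.copy()
    ssr = _ssr(theta, x, y, dT, dP)
    if not np.isfinite(ssr) or not _in_support(theta, prior):
        raise RuntimeError("initial point outside posterior support")
    sigma2 = max(ssr / n, 1e-6)
    prop_sd = prop_sd0.copy()

    kept = iterations - burn_in
    out = np.empty((kept, 7))
    acc_window = np.zeros(6)
    acc_post = np.zeros(6)
    shape_post = prior.ig_shape + 0.5 * n

    for it in range(iterations):
        for p in range(6):
            prop = theta.copy()
            prop[p] += rng.normal(0.0, prop_sd[p])
            if _in_support(prop, prior):
                ssr_p = _ssr(prop, x, y, dT, dP)
                if np.isfinite(ssr_p):
                    log_r = (ssr - ssr_p) / (2.0 * sigma2)
                    if log_r >= 0.0 or np.log(rng.random()) < log_r:
                        theta = prop
                        ssr = ssr_p
                        acc_window[p] += 1.0
                        if it >= burn_in:
                            acc_post[p] += 1.0
        rate_post = prior.ig_rate + 0.5 * ssr
        sigma2 = rate_post / rng.gamma(shape_post)

        if it < burn_in and (it + 1) % adapt_window == 0:
            rates = acc_window / adapt_window
            prop_sd *= np.where(rates > target_accept, 1.15, 0.87)
            acc_window[:] = 0.0

        if it >= burn_in:
            j = it - burn_in
            out[j, :6] = theta
            out[j, 6] = sigma2

    acc_rates = acc_post / max(kept, 1)
    if np.any(acc_rates == 0.0):
        dead = [PARAM_NAMES[i] for i in range(6) if acc_rates[i] == 0.0]
        raise RuntimeError(
            f"chain rejected every post-burn-in proposal for {dead}; "
            "rescale the proposal SDs or extend burn-in"
        )
    return out, acc_rates


def run_mcmc(
    plots: pd.DataFrame,
    prior: PriorSpec | None = None,
    chains: int = 5,
    iterations: int = 10_000,
    burn_in: int | None = None,
    seed: int = 0,
    t_bar: float | None = None,
    p_bar: float | None = None,
    init_jitter: float = 0.1,
) -> PosteriorDraws:
    """Sample the posterior for one forest type.

    Parameters
    ----------
    plots
        Plot table rows of a single forest type (ages > 0).
    prior
        :class:`PriorSpec`; defaults to the flat variant.
    chains, iterations, burn_in
        Independent chains, iterations per chain, and burn-in (default half
        of ``iterations``); only post-burn-in draws are stored.
    seed
        Master seed; each chain uses an independent stream derived from
        ``(seed, chain)``, so results do not depend on execution order.
    t_bar, p_bar
        Climate centers. Default: means of the supplied plots (the
        current-period convention when fitting current data).
    init_jitter
        Relative SD of the lognormal-style dispersion applied to each
        chain's starting point around the least-squares fit.
    """
    prior = prior or PriorSpec()
    if burn_in is None:
        burn_in = iterations // 2
    if not 0 <= burn_in < iterations:
        raise ValueError("need 0 <= burn_in < iterations")
    if len(plots) < 8:
        raise ValueError(f"need >= 8 plots to fit 7 parameters, got {len(plots)}")
    ftype_vals = plots["forest_type"].unique()
    if len(ftype_vals) != 1:
        raise ValueError(f"plots span multiple forest types: {sorted(ftype_vals)}")
    if t_bar is None:
        t_bar = float(plots["mat"].mean())
    if p_bar is None:
        p_bar = float(plots["map"].mean())

    x, y, dT, dP = _design(plots, t_bar, p_bar)
    if np.any(x <= 0):
        raise ValueError("stand ages must be positive")
    theta_hat = _init_theta(x, y)

    # scale-aware initial proposal SDs; adaptation refines them per chain
    sd_y = max(float(np.std(y)), 1.0)
    sd_T = max(float(np.std(dT)), 1e-3)
    sd_P = max(float(np.std(dP)), 1e-3)
    prop_sd0 = np.array(
        [
            0.05 * max(abs(theta_hat[0]), sd_y),
            0.05 * sd_y / sd_T,
            0.05 * sd_y / sd_P,
            0.05 * max(abs(theta_hat[3]), 10.0),
            0.5 / sd_T,
            0.5 / sd_P,
        ]
    )

    kept = iterations - burn_in
    draws = np.empty((chains, kept, 7))
    acc = np.empty((chains, 6))
    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        for _ in range(100):
            jitter = rng.normal(0.0, init_jitter, size=6)
            theta0 = theta_hat * (1.0 + jitter)
            theta0[1] += sd_y / sd_T * jitter[1]
            theta0[2] += sd_y / sd_P * jitter[2]
            if prior.variant == "positive_truncated":
                theta0[0] = abs(theta0[0])
                theta0[3] = abs(theta0[3])
            if _in_support(theta0, prior) and np.isfinite(_ssr(theta0, x, y, dT, dP)):
                break
        else:
            theta0 = theta_hat
        draws[c], acc[c] = _run_chain(
            x, y, dT, dP, prior, iterations, burn_in, rng, theta0, prop_sd0
        )

    return PosteriorDraws(
        forest_type=str(ftype_vals[0]),
        draws=draws,
        burn_in=burn_in,
        seed=seed,
        t_bar=t_bar,
        p_bar=p_bar,
        acceptance=acc,
    )


def fit_forest_type(plots: pd.DataFrame, centers: pd.DataFrame | None = None, **kw) -> PosteriorDraws:
    """Fit one forest type, taking centers from a :func:`climate_centers` table."""
    if centers is not None:
        ftype = plots["forest_type"].iloc[0]
        row = centers.loc[centers["forest_type"] == ftype]
        if row.empty:
            raise ValueError(f"no climate centers for forest type {ftype!r}")
        kw.setdefault("t_bar", float(row["t_bar"].iloc[0]))
        kw.setdefault("p_bar", float(row["p_bar"].iloc[0]))
    return run_mcmc(plots, **kw)


def fit_all_types(
    plots: pd.DataFrame, prior: PriorSpec | None = None, chains: int = 5,
    iterations: int = 10_000, burn_in: int | None = None, seed: int = 0,
) -> dict[str, PosteriorDraws]:
    """Fit every forest type separately on its current-period plots.

    Climate centers are the current-period per-type means and are stored on
    each result for reuse by hindcast and forecast.
    """
    current = plots.loc[plots["period"] == "current"]
    centers = climate_centers(current, "current")
    out: dict[str, PosteriorDraws] = {}
    for i, (ftype, sub) in enumerate(current.groupby("forest_type", sort=True)):
        out[str(ftype)] = fit_forest_type(
            sub, centers, prior=prior, chains=chains, iterations=iterations,
            burn_in=burn_in, seed=seed + i,
        )
    return out


# ---------------------------------------------------------------------------
# Convergence diagnostics and posterior summaries


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain segment at frequency zero.

    Bartlett-window (Newey-West) estimate with lag truncation n^(1/3),
    the standard long-run variance estimator for MCMC standard errors.
    """
    n = x.size
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0.0:
        raise ValueError("zero-variance segment: degenerate chain")
    lag_max = min(int(round(n ** (1.0 / 3.0))), n - 1)
    s = c0
    for lag in range(1, lag_max + 1):
        cl = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (lag_max + 1.0)) * cl
    return max(s, 1e-300)


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score for one parameter trace.

    Compares the mean of the first ``first_frac`` of the chain against the
    mean of the last ``last_frac``, with variances from spectral density at
    zero (so autocorrelation inflates the standard errors). |z| < 2 passes
    by convention; large |z| flags a non-stationary (unconverged) chain.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError(f"trace too short for Geweke diagnostic (n={n} < 100)")
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    a, b = x[:n1], x[n - n2:]
    var = _spectral_density_zero(a) / n1 + _spectral_density_zero(b) / n2
    return float((a.mean() - b.mean()) / np.sqrt(var))


def geweke_table(draws: PosteriorDraws, threshold: float = 2.0) -> pd.DataFrame:
    """Geweke z per (chain, parameter), with a pass flag at |z| < threshold."""
    rows = []
    for c in range(draws.chains):
        for p, name in enumerate(PARAM_NAMES):
            z = geweke_z(draws.draws[c, :, p])
            rows.append({"chain": c, "param": name, "z": z, "passed": abs(z) < threshold})
    return pd.DataFrame(rows)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Pooled posterior mean, SD, and central 95% credible interval.

    Quantiles use linear interpolation (numpy default) on the post-burn-in
    draws pooled across chains.
    """
    pooled = draws.pooled()
    q = np.quantile(pooled, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "param": list(PARAM_NAMES),
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[1],
        }
    )
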