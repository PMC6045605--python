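import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from regrowth import fit_growth_xy
from regrowth.hbmodel import (
    PARAM_NAMES,
    ForestTypeParams,
    PosteriorDraws,
    PriorSpec,
    geweke_z,
    log_likelihood,
    log_posterior,
    log_prior,
    mu_k_of_climate,
    run_mcmc,
    summarize_posterior,
)
from regrowth.synthetic import ClimateLaw, generate_dataset, single_type_config

from conftest import make_plot_table


def _params(**kw):
    base = dict(
        forest_type="typeA", beta0=355.0, beta1=14.0, beta2=0.177,
        gamma0=106.0, gamma1=-1.20, gamma2=0.00679, sigma2=1600.0,
        t_bar=8.0, p_bar=1200.0,
    )
    base.update(kw)
    return ForestTypeParams(**base)


class TestMuKOfClimate:
    def test_average_climate_returns_intercepts(self):
        mu, k = mu_k_of_climate(_params(), 8.0, 1200.0)
        assert mu == pytest.approx(355.0)
        assert k == pytest.approx(106.0)

    def test_one_degree_warming_raises_asymptote_by_beta1(self):
        mu, _ = mu_k_of_climate(_params(), 9.0, 1200.0)
        assert mu == pytest.approx(369.0)

    def test_ten_degree_warming_lowers_half_saturation_age(self):
        _, k = mu_k_of_climate(_params(), 18.0, 1200.0)
        assert k == pytest.approx(94.0)


class TestLogLikelihood:
    def test_single_plot_at_the_mean_with_unit_variance(self):
        p = _params(sigma2=1.0)
        mu, k = mu_k_of_climate(p, 10.0, 1100.0)
        age = 75.0
        agb = float(mu * age / (k + age))
        plots = make_plot_table(n=1, stand_age=age, agb=agb, mat=10.0, map=1100.0)
        assert log_likelihood(plots, p) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_independently_coded_normal_densities(self):
        # brute-force oracle: per-plot normal log-density summed in pure python
        p = _params()
        plots = make_plot_table(n=5, seed=12)
        expected = 0.0
        for _, row in plots.iterrows():
            mu = p.beta0 + p.beta1 * (row["mat"] - p.t_bar) + p.beta2 * (row["map"] - p.p_bar)
            k = p.gamma0 + p.gamma1 * (row["mat"] - p.t_bar) + p.gamma2 * (row["map"] - p.p_bar)
            m = mu * row["stand_age"] / (k + row["stand_age"])
            expected += (
                -0.5 * math.log(2 * math.pi * p.sigma2)
                - (row["agb"] - m) ** 2 / (2 * p.sigma2)
            )
        assert log_likelihood(plots, p) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_denominator_gives_minus_inf(self):
        p = _params(gamma0=5.0, gamma1=-50.0)
        plots = make_plot_table(n=1, stand_age=2.0, mat=18.0, map=1200.0)
        assert log_likelihood(plots, p) == -np.inf

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError, match="sigma2"):
            log_likelihood(make_plot_table(n=1), _params(sigma2=0.0))


class TestLogPrior:
    def test_flat_inside_bounds_is_constant_in_theta(self):
        prior = PriorSpec()
        a = log_prior(_params(), prior)
        b = log_prior(_params(beta0=12.0, gamma1=4000.0), prior)
        assert a == pytest.approx(b)

    def test_outside_bounds_is_minus_inf(self):
        assert log_prior(_params(beta1=2e5), PriorSpec()) == -np.inf

    def test_positive_truncation_excludes_negative_intercepts(self):
        prior = PriorSpec(variant="positive_truncated")
        assert log_prior(_params(gamma0=-1.0), prior) == -np.inf
        assert np.isfinite(log_prior(_params(), prior))

    def test_inverse_gamma_term_matches_independent_formula(self):
        # hand-coded IG(shape a, rate b) log-density as the oracle
        a = b = 1e-5
        prior = PriorSpec(ig_shape=a, ig_rate=b)
        for s2 in (0.5, 1.0, 1600.0):
            got = log_prior(_params(sigma2=s2), prior) - log_prior(_params(sigma2=1.0), prior)
            def ig(x):
                return a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(x) - b / x
            assert got == pytest.approx(ig(s2) - ig(1.0), abs=1e-12)

    def test_log_posterior_is_likelihood_plus_prior(self):
        plots = make_plot_table(n=20, seed=3)
        prior = PriorSpec()
        p = _params()
        assert log_posterior(plots, p, prior) == pytest.approx(
            log_likelihood(plots, p) + log_prior(p, prior)
        )


class TestRunMcmc:
    def test_same_seed_gives_identical_draws(self, single_type_data):
        plots, _, _ = single_type_data
        sub = plots.iloc[:200]
        a = run_mcmc(sub, chains=2, iterations=600, seed=9)
        b = run_mcmc(sub, chains=2, iterations=600, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_chains_are_seed_derived_not_order_dependent(self, single_type_data):
        plots, _, _ = single_type_data
        sub = plots.iloc[:200]
        five = run_mcmc(sub, chains=3, iterations=600, seed=9)
        two = run_mcmc(sub, chains=2, iterations=600, seed=9)
        np.testing.assert_array_equal(five.draws[:2], two.draws)

    def test_parameter_recovery_within_posterior_uncertainty(self, small_fit):
        sub, truth, draws = small_fit
        s = summarize_posterior(draws)
        t = [truth.beta0, truth.beta1, truth.beta2, truth.gamma0,
             truth.gamma1, truth.gamma2, truth.sigma2]
        z = (s["mean"].to_numpy() - t) / s["sd"].to_numpy()
        assert np.all(np.abs(z) < 4.0)

    def test_flat_prior_posterior_mean_tracks_ml_fit(self):
        # no climate effects in the generator: the Monod ML fit and the
        # Bayesian posterior mean must agree within 2 posterior SDs
        cfg = single_type_config(n_plots=1000, seed=21)
        cfg = dataclasses.replace(cfg, climate_law=ClimateLaw(temp_sd=0.0, precip_sd=0.0))
        plots, _ = generate_dataset(cfg)
        ml = fit_growth_xy(plots["stand_age"], plots["agb"], "monod")
        draws = run_mcmc(plots, chains=2, iterations=4000, seed=2)
        s = summarize_posterior(draws).set_index("param")
        for par, mlv in (("beta0", ml.params["mu"]), ("gamma0", ml.params["k"])):
            assert abs(s.loc[par, "mean"] - mlv) < 2.0 * s.loc[par, "sd"]

    def test_no_climate_information_leaves_slopes_diffuse(self):
        cfg = single_type_config(n_plots=300, seed=22)
        cfg = dataclasses.replace(cfg, climate_law=ClimateLaw(temp_sd=0.0, precip_sd=0.0))
        plots, _ = generate_dataset(cfg)
        draws = run_mcmc(plots, chains=2, iterations=3000, seed=4)
        s = summarize_posterior(draws).set_index("param")
        # beta1 is unidentified: its credible interval dwarfs beta0's
        assert s.loc["beta1", "sd"] > 10.0 * s.loc["beta0", "sd"]

    def test_initialization_invariance_within_mc_error(self, single_type_data):
        from regrowth.hbmodel import _spectral_density_zero

        plots, _, _ = single_type_data
        sub = plots.iloc[:400]
        tight = run_mcmc(sub, chains=2, iterations=4000, seed=31, init_jitter=0.0)
        wide = run_mcmc(sub, chains=2, iterations=4000, seed=32, init_jitter=0.3)

        def mcse(d, p):
            per_chain = [
                _spectral_density_zero(d.draws[c, :, p]) / d.kept
                for c in range(d.chains)
            ]
            return np.sqrt(np.mean(per_chain) / d.chains)

        for p in range(7):
            diff = tight.pooled()[:, p].mean() - wide.pooled()[:, p].mean()
            se = np.hypot(mcse(tight, p), mcse(wide, p))
            assert abs(diff) < 4.0 * se, PARAM_NAMES[p]

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            run_mcmc(make_plot_table(n=5), iterations=100)

    def test_credible_interval_coverage_smoke(self, small_fit):
        _, truth, draws = small_fit
        s = summarize_posterior(draws).set_index("param")
        t = dict(zip(PARAM_NAMES, [truth.beta0, truth.beta1, truth.beta2,
                                   truth.gamma0, truth.gamma1, truth.gamma2,
                                   truth.sigma2]))
        covered = sum(
            s.loc[p, "q2.5"] <= t[p] <= s.loc[p, "q97.5"] for p in PARAM_NAMES
        )
        assert covered >= 5  # most of the seven parameters on a single run


class TestGeweke:
    def test_identical_segment_means_give_zero(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=100)
        # first 10% is one copy of the pattern, last 50% five copies:
        # identical segment means by construction, so z must vanish
        chain = np.tile(pattern, 10)
        assert geweke_z(chain) == pytest.approx(0.0, abs=1e-12)

    def test_iid_normal_chains_pass(self):
        zs = [
            geweke_z(np.random.default_rng(seed).normal(size=2000))
            for seed in range(10)
        ]
        assert np.mean(np.abs(zs) < 3.0) >= 0.9

    def test_linear_drift_is_detected(self):
        rng = np.random.default_rng(1)
        chain = np.linspace(0.0, 5.0, 5000) + rng.normal(size=5000)
        assert abs(geweke_z(chain)) > 4.0

    def test_short_or_constant_chains_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            geweke_z(np.zeros(50))
        with pytest.raises(ValueError, match="zero-variance"):
            geweke_z(np.zeros(1000))


class TestSummarize:
    @staticmethod
    def _draws_from(arr):
        arr = np.asarray(arr, dtype=float)
        block = np.tile(arr[None, :, None], (1, 1, 7))
        return PosteriorDraws("t", block, burn_in=0, seed=0, t_bar=0.0, p_bar=0.0)

    def test_constant_draws_collapse(self):
        s = summarize_posterior(self._draws_from(np.full(100, 3.5)))
        assert (s["mean"] == 3.5).all()
        assert (s["sd"] == 0.0).all()
        assert (s["q2.5"] == 3.5).all() and (s["q97.5"] == 3.5).all()

    def test_standard_normal_quantiles(self):
        draws = self._draws_from(np.random.default_rng(5).normal(size=10_000))
        s = summarize_posterior(draws)
        assert s["q2.5"].iloc[0] == pytest.approx(-1.96, abs=0.1)
        assert s["q97.5"].iloc[0] == pytest.approx(1.96, abs=0.1)

    def test_pooled_and_per_chain_means_agree_on_converged_run(self, small_fit):
        _, _, draws = small_fit
        pooled = draws.pooled().mean(axis=0)
        per_chain = draws.draws.mean(axis=1)
        spread = np.abs(per_chain - pooled).max(axis=0)
        assert np.all(spread < 5.0 * draws.pooled().std(axis=0) / np.sqrt(10))

    def test_frame_round_trip(self, small_fit):
        _, _, draws = small_fit
        df = draws.to_frame()
        back = PosteriorDraws.from_frame(
            draws.forest_type, df, draws.burn_in, draws.seed, draws.t_bar, draws.p_bar
        )
        np.testing.assert_array_equal(back.draws, draws.draws)
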