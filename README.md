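# regrowth

Hierarchical Bayesian modelling of forest aboveground-biomass recovery and
its remaining growth potential under climate change.

North American forests are a major carbon sink largely because they are
still recovering from past land use. How much more carbon can they take up?
`regrowth` answers this with a forest-inventory-style analysis: aboveground
biomass *y* (Mg ha⁻¹) accumulates with stand age *x* (yr) along a Monod
(Michaelis–Menten) curve, and local climate bends the trajectory,

    y_ij = μ_ij · x_ij / (k_ij + x_ij) + ε_ij,      ε_ij ~ N(0, σ_j²)
    μ_ij = β₀j + β₁j (T_ij − T̄_j) + β₂j (P_ij − P̄_j)
    k_ij = γ₀j + γ₁j (T_ij − T̄_j) + γ₂j (P_ij − P̄_j)

where μ is the asymptotic saturated biomass, *k* the half-saturation age,
and *T*, *P* are mean annual temperature and precipitation centered on
forest-type means. Each forest type *j* is fitted separately by MCMC under
noninformative priors. The fitted model is validated by hindcasting an
earlier inventory period and by 75/25 cross-validation with a spatially
modified t-test (autocorrelation-corrected degrees of freedom), then
extrapolated to future periods (2020s/2050s/2080s) under emission-scenario
climate (RCP4.5/RCP8.5) assuming no further disturbance — a best case. The
ratio of current to best-case future biomass quantifies how saturated the
carbon sink already is.

The package is aimed at ecologists and biostatisticians who want a tested,
reusable, fully synthetic-data-testable implementation of this pipeline:
since national inventory archives are restricted, a seeded generator
reproduces the data's statistical structure (23 forest types, right-skewed
stand ages to 1000 yr, climate gradients, type-level noise) so every stage
can be verified end to end. See `docs/methods.md` for the model, sampler,
and design choices.

## Worked example

```python
import regrowth as rg

# one forest type at the generator's default study conditions:
# beta0=355, beta1=14, beta2=0.177, gamma0=106, gamma1=-1.20,
# gamma2=0.00679, sigma=40, n=2000 plots
cfg = rg.single_type_config(n_plots=2000, seed=1)
plots, (truth,) = rg.generate_dataset(cfg)

draws = rg.run_mcmc(plots, chains=5, iterations=10_000, seed=2)
print(rg.summarize_posterior(draws))
```

A run of this recovery experiment (via `scripts/acceptance.py --seed 1`)
prints:

```
posterior_mean_asymptotic_biomass_mg_ha: 357.4 (n=2000)
posterior_mean_asymptote_temperature_effect_mg_ha_per_degc: 12.26 (n=2000)
posterior_mean_asymptote_precipitation_effect_mg_ha_per_mm: 0.1797 (n=2000)
posterior_mean_half_saturation_age_yr: 108 (n=2000)
posterior_mean_half_saturation_temperature_effect_yr_per_degc: -2.064 (n=2000)
posterior_mean_half_saturation_precipitation_effect_yr_per_mm: 0.006309 (n=2000)
```

The sampler recovers the generating parameters: saturated biomass 357.4
vs the true 355 Mg ha⁻¹, half-saturation age 108 vs 106 yr, and the four
climate-effect slopes within posterior uncertainty of their true values.
The same seed-1 run continues through the multi-type pipeline:

```
saturating_model_aic_win_rate_pct: 100 (n=20)
in_sample_spatial_correlation: 0.9026 (n=3929)
cv_spatial_correlation: 0.8936 (n=994)
observed_current_biomass_mg_ha: 141.8 (n=4000)
forecast_biomass_2020s_rcp85_mg_ha: 170.6 (n=4000)
forecast_biomass_2050s_rcp85_mg_ha: 216.6 (n=4000)
forecast_biomass_2080s_rcp85_mg_ha: 258.1 (n=4000)
mean_saturation_ratio_2080s_rcp85: 0.5145 (n=4000)
```

AIC prefers a saturating growth form in every replicate; gridded observed
and predicted biomass correlate strongly in-sample (r = 0.90) and
out-of-sample (r = 0.89, spatially modified t-test); the biomass cohort
mean climbs from 142 Mg ha⁻¹ now to a best-case 258 Mg ha⁻¹ by the 2080s
under high emissions, so current biomass averages 51% of its modelled
potential on this synthetic landscape.

## Command line

Every stage is also a subcommand of the `regrowth` CLI:

```bash
regrowth simulate --n-types 5 --n-plots 800 --seed 1 --out data/
regrowth select-model --plots data/plots.csv --out fits.csv
regrowth fit --plots data/plots.csv --chains 5 --iters 10000 --seed 1 --out draws/
regrowth forecast --plots data/plots.csv --climate data/scenario_climate.csv \
    --scenario RCP8.5 --period 2080s --draws draws/ --out future.csv
regrowth ratio --current data/plots.csv --future future.csv --out ratio.csv
regrowth validate --plots data/plots.csv --seed 1 --out cv.json
regrowth run --config run.json        # full pipeline with artifact manifest
```

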