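# Methods

## Model

For plot *i* of forest type *j*, aboveground biomass *y* (Mg ha⁻¹) follows a
Monod (Michaelis–Menten) recovery curve in stand age *x* (yr) with additive
normal error:

    y_ij = μ_ij · x_ij / (k_ij + x_ij) + ε_ij,   ε_ij ~ N(0, σ_j²)

The asymptotic saturated biomass μ and the half-saturation age *k* (the age
at which biomass reaches μ/2) are linear in climate, centered on per-type
means so the intercepts are interpretable as "the trajectory on an average
climate":

    μ_ij = β₀j + β₁j (T_ij − T̄_j) + β₂j (P_ij − P̄_j)
    k_ij = γ₀j + γ₁j (T_ij − T̄_j) + γ₂j (P_ij − P̄_j)

with *T* mean annual temperature (°C) and *P* mean annual precipitation
(mm yr⁻¹). Each forest type is fitted separately; there are no cross-type
hyperpriors. The model embodies a space-for-time substitution: spatial
climate variation across plots stands in for the temporal climate variation
a recovering stand experiences.

Climate centers are computed over **current-period plots only** and reused
unchanged for hindcast and forecast. This keeps β₀ and γ₀ anchored to the
same reference climate across periods; pooling periods would silently shift
the intercepts' meaning.

### Priors

Noninformative: U(−10⁵, 10⁵) on the six regression parameters and
inverse-gamma IG(shape = 10⁻⁵, rate = 10⁻⁵) on σ². The shape/rate
parametrization is assumed (both conventions exist; with these magnitudes
the prior is vague either way). A `positive_truncated` variant restricts
β₀, γ₀ to (0, 10⁵), encoding positive saturated biomass and half-saturation
age; the two variants give nearly identical posteriors on informative data.

### Support rule

Flat priors alone do not prevent parameter points where some plot's Monod
denominator k_ij + x_ij is nonpositive. Such points receive log-likelihood
−∞ and are always rejected. This is one defensible resolution of a choice
the model statement leaves open; it guarantees every retained draw defines
a finite, physical mean for every observed plot.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs:

- one scalar Gaussian random-walk block per regression parameter, proposal
  SDs tuned every 50 burn-in iterations toward ~0.3 acceptance (×1.15 when
  above, ×0.87 when below), frozen after burn-in;
- σ² drawn exactly by a conjugate Gibbs step, IG(shape + n/2,
  rate + SSR/2), available because the errors are normal;
- defaults: 5 chains, 10,000 iterations, burn-in half, thinning 1. These are
  the package's working defaults for simulation studies; chains and
  iterations scale up freely through configuration for production fits;
- chain *c* draws from `numpy.random.default_rng([seed, c])`, so results are
  reproducible and independent of chain execution order;
- chains initialize at a climate-free Monod least-squares fit with
  per-chain relative jitter (default 10%); a chain that rejects every
  post-burn-in proposal for some block raises rather than returning
  degenerate output.

Convergence is assessed with Geweke z-scores (first 10% vs last 50% of each
chain, variances from the spectral density at zero estimated with a
Bartlett window of n^⅓ lags). |z| ≥ 2 produces a warning artifact, not an
abort: the diagnostic flags, the analyst decides. Posterior summaries are
empirical means, SDs, and 2.5/97.5% quantiles (linear interpolation) of the
post-burn-in draws pooled across chains.

## Growth-model selection

Before the hierarchical fit, four origin-constrained growth forms are
compared per forest type: linear βx, exponential β·log(x+1),
Chapman–Richards μ(1−e^(−kx)), and Monod μx/(k+x). Fits are maximum
likelihood under i.i.d. normal errors — closed-form least squares for the
two linear-in-β forms, bounded nonlinear least squares with a 3×3
multi-start grid (μ ∈ {0.5, 1, 2}·max y; half-saturation ∈
{0.25, 1, 4}·median x) for the saturating forms, because Monod-type fits
are ill-conditioned when the data do not reach saturation. σ uses the ML
estimator (SSR/n, not SSR/(n−p)) so AIC = 2p − 2·logL is
textbook-consistent, with σ counted in p. A perfect fit floors σ at 10⁻⁸
Mg ha⁻¹ and flags the result to keep the log-likelihood finite. Ties
(ΔAIC < 2) break toward fewer parameters, then toward Monod, whose two
parameters have direct ecological readings.

## Hindcast, forecast, and the saturation ratio

Hindcast (past period) and forecast (future periods) are the same
noise-free operator ŷ = μ̂·x/(k̂+x) applied to different covariates;
predictions carry parameter uncertainty only, with no residual noise term.
The default prediction path plugs in posterior means (point estimates); a
posterior path propagates every retained draw (evenly thinned to ≤ 2000)
and reports 95% credible intervals. Draws giving a nonpositive denominator
at a prediction point are dropped from that plot's predictive distribution;
negative predicted means are floored at 0 (biomass is physical) and
counted.

Future stand age extrapolates the observed age to the period midpoint:
2025, 2055, 2085 for the 2020s/2050s/2080s (midpoint-of-decade is the
least-surprising convention; configurable). Projected climate replaces the
covariates; the centers T̄_j, P̄_j stay at their current-period values.

The saturation ratio current/future is reported per plot and as cohort
mean ± SD with 5/25/50/75/95% quantiles. The numerator defaults to
**observed** current biomass (modelled current is available as an option —
the source convention is ambiguous on this point); plots with nonpositive
future means are excluded and counted.

## Spatial evaluation

Plot-level fields are averaged on a 10-arcmin (1/6°) geographic grid with
half-open cells [i/6, (i+1)/6), so boundary plots join the higher-index
cell. Observed-vs-predicted agreement is the Pearson correlation of cell
means, with significance from a spatially modified t-test: Dutilleul's
effective sample size

    M = 1 + tr(CΣ_aC)·tr(CΣ_bC) / tr(CΣ_aCΣ_bC)

where C is the centering matrix and Σ_a, Σ_b are correlation matrices
implied by each field's correlogram over 10 equal-count great-circle
distance classes (spherical law of cosines, adequate at continental
scale). M reduces to n for independent fields, is capped at n, and sets
the degrees of freedom of the two-sided t reference distribution. The
variant choice matters mildly; this is the standard
Clifford–Richardson–Hémon/Dutilleul construction.

Cross-validation is a random 75/25 **plot-level** split (floor rule for the
training size): only the evaluation is spatial (gridded,
autocorrelation-corrected). Types with fewer than 8 training plots (the
parameter count plus one) are excluded from fitting and reported.

## Synthetic data

The generator emulates a continental inventory compilation: 23 forest
types by default, each with a climate envelope (type temperature means
spread over 0–20 °C, SD 2 °C within type; precipitation means 400–2000 mm,
SD 150 mm), right-skewed lognormal stand ages (median 60 yr, log-SD 1.0,
truncated to [1, 1000] yr), and biomass drawn from the model above with
per-type parameters sampled around the continental-scale averages
(β₀ = 355 Mg ha⁻¹, γ₀ = 106 yr, β₁ = 14 Mg ha⁻¹ °C⁻¹,
β₂ = 0.177 Mg ha⁻¹ mm⁻¹, γ₁ = −1.20 yr °C⁻¹, γ₂ = 0.00679 yr mm⁻¹).
σ_j defaults to U(20, 60) Mg ha⁻¹ — a stand-in chosen to match the visual
spread of biomass–age scatter at these scales, since type-level residual
SDs are not published. Future-scenario climate offsets default to
CMIP5-ensemble-like values (e.g. +4.8 °C, +80 mm for the high-emission
2080s). All randomness flows from one seed through named generator
streams; output is bit-reproducible.

Negative biomass draws are clipped at zero, with a warning when more than
1% of draws clip. What the generator does **not** emulate: spatial
clustering of plots (coordinates are uniform over the bounding box, except
for an optional Gaussian-process field used to exercise the modified
t-test), measurement error in stand age, disturbance histories,
heteroscedastic or skewed biomass errors, and covariance between climate
and age. Passing tests therefore demonstrate correctness and calibration
of the machinery under the model's own assumptions, not fidelity to real
inventory data.

### Known limitation: zero-truncation bias

At the default noise level (σ = 40 Mg ha⁻¹) with lognormal ages, roughly
3% of generated biomass values clip at zero. The fitted model has no
truncation term, so the σ² posterior is biased low by a few percent; at
n = 2000 this exceeds the width of its own credible interval, and σ²
interval coverage over replicates falls below nominal (the regression
parameters are essentially unaffected — their posterior means stay within
3 posterior SDs of truth). This is the expected behaviour of a
well-specified-model fitter on mildly truncated data, and it is why the
generator warns when clipping is non-rare. Analyses that need calibrated
σ² intervals should use age distributions or noise levels for which
truncation is rare (e.g. minimum age ≈ 50 yr at σ = 40).

## Numerical choices and degenerate inputs

- Plot CSVs are written with shortest round-trip decimals and parsed with
  correctly rounded `float()`, so write→read is bit-exact.
- Quantiles everywhere use numpy's linear interpolation.
- Sample-size guards: ≥ 8 plots per type for the 7-parameter MCMC fit,
  ≥ p+1 for growth fits, ≥ 10 common cells and ≥ 100 trace points for the
  modified t-test and Geweke diagnostic; zero-variance segments or fields
  raise rather than returning NaN.
- Pipeline runs are pure functions of (inputs, config, seed); the manifest
  of SHA-256 artifact hashes is the determinism contract, verified by
  double-run tests.

## Problem sizes in the test suite

Simulation-based tests run at deliberately moderate sizes chosen as the
package's own defaults for desk-scale verification: single-type recovery
at n = 2000 plots with 5 chains × 10,000 iterations, model-selection
replicates at n = 1000, t-test calibration on 200 cells × 500 simulations,
and pipeline smoke runs with 2 types × 200 plots. These sizes make every
claim in the suite recomputable in minutes on one CPU while keeping Monte
Carlo error well below the tested tolerances.
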