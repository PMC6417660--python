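# Methods

## Model

`divehmm` fits hidden Markov models to per-dive summaries of a
time-depth record. Each dive *t* contributes a positive response triple
**X**_t = (MD_t, DT_t, PD_t): maximum depth (m), dive duration (min) and
post-dive surface time (min). An unobserved behavioural state
C_t ∈ {1, …, m} follows a Markov chain with time-varying transition
matrix Ω(t); given C_t = i, **X**_t is drawn from the state's emission
distribution f_i and is conditionally independent of everything else.
The likelihood is the usual matrix product

    L_T = δ P(x_1) Ω(t_1) P(x_2) ⋯ Ω(t_{T−1}) P(x_T) 1,

with P(x) = diag(f_1(x), …, f_m(x)) and δ the initial distribution
(uniform by default; with thousands of dives its influence is
negligible). The transition out of dive t is governed by the covariates
of dive t (the origin dive) — this indexing is used consistently in the
likelihood, the decoder and the simulator.

### Emission families

Four families are available, all right-skewed on (0, ∞)³:

* `gamma_indep` — independent gamma marginals, shape μ and scale σ per
  coordinate and state (mean μσ, variance μσ²).
* `lognormal_indep` — independent log-normal marginals with log-mean μ
  and log-SD σ.
* `lognormal_dep` — log **X** trivariate normal with log-scale
  correlation ρ between coordinates. The response-scale correlation
  implied by a log-correlation ρ and log-SDs σ₁, σ₂ is
  (exp(ρσ₁σ₂) − 1) / √((exp(σ₁²) − 1)(exp(σ₂²) − 1)).
* `gamma_dep` — the same gamma marginals coupled by a Gaussian copula.
  The literature this framework comes from names a dependent gamma
  distribution without printing its density; the copula construction is
  this package's interpretation. It preserves the gamma marginals and
  uses a single dependence parameter per state, but AIC comparisons with
  other dependent-gamma constructions are indicative only. Its
  response-scale correlation has no closed form and is computed by
  two-dimensional Gauss–Hermite quadrature (48 nodes, accurate to ~1e-12
  against Monte Carlo at the parameter scales used here).

By default only the MD–DT pair is dependent (one ρ per state): empirical
correlations with PD are an order of magnitude smaller than the MD–DT
correlation within depth bands, and restricting the dependence improves
convergence. A full 3×3 dependence structure is available
(`dependence="full"`) for robustness checks; it is parametrised by
canonical partial correlations so the working space stays unconstrained.

### Covariates and transition probabilities

Three covariate processes feed back into the transition probabilities:

* τ_t — hours since the end (resurfacing) of the last *deep dive*
  (≥ 350 m by default). Before the first deep dive τ counts hours since
  the record start and the rows are flagged so the burn-in can be
  dropped. A start-to-start reference is available via
  `tau_reference="start"`.
* d_t — the number of consecutive deep dives immediately before dive t
  (0 whenever the previous dive was not deep). It enters its spline as a
  real value.
* h_t — hour of day at dive initiation, in [0, 24).

Off-diagonal predictors are η_ij(t) = intercept + spline terms; the
diagonal is pinned at η_ii = 0 and rows map to probabilities by a
softmax (computed with per-row max subtraction). τ and d enter as
natural cubic splines with 3 df; the spline bases are built R-`ns()`
style (cubic B-splines projected onto the natural constraints, linear
beyond the boundary knots) with interior knots at the 1/3 and 2/3
quantiles of the training covariate and boundary knots at its range,
frozen at fit time and stored with the model. Whether quantile-based or
equally spaced knots were used in the original analyses is not stated;
quantile placement is the conventional default. Hour enters through a
periodic cubic B-spline with period 24 h (matching value and first two
derivatives at 0/24), built from df+1 uniformly spaced wrapped
B-splines with the first dropped — the full wrapped set sums to one,
which would alias the intercept exactly.

Named presets `model1`–`model4` give the standard 3-state term layouts
(diurnal terms everywhere; τ terms out of states 1–2; d terms out of
state 3, the deep state); they generalise to other m by treating the
deepest state's rows as the d-carrying ones, which reproduces the
published parameter counts for m = 2 (28) and m = 4 (112). Arbitrary
structures are available through `CovariateModel.from_config`.

τ is used on its natural hour scale; a `log1p` transform can be applied
upstream by the caller if desired.

## Estimation

The log-likelihood is computed by the scaled forward recursion
(normalised forward vector, accumulated log scale factors; O(Tm²),
numba-compiled). Optimisation is quasi-Newton (L-BFGS-B) on an
unconstrained working scale: log for positive parameters, artanh for
correlations (partial correlations in the full-dependence case),
identity for log-normal log-means and all transition coefficients.
Convergence uses relative objective change 1e-8 and projected-gradient
norm 1e-5.

For the log-normal families the score is computed analytically from one
forward–backward pass: state posteriors weight the emission derivatives
(Gaussian sufficient statistics chained through the σ/ρ
parametrisation), and transition-pair posteriors give
∂ℓ/∂η_ij(t) = ξ_t(i,j) − γ_t(i) ω_ij(t), mapped to coefficients through
the frozen design matrices. The gamma families (and the full-dependence
option) use finite-difference gradients; they are markedly slower, which
is consistent with the published runtime comparisons. The analytic score
is verified against central differences in the test suite.

Multi-start protocol: emission starts come from an m-component
univariate Gaussian mixture fitted to log MD (components sorted by mean,
per-component moments seeding all three coordinates; quantile-sliced
moment estimates as fallback); the MD–DT dependence parameter starts at
the empirical log-scale correlation; start 0 uses zero transition
coefficients, later starts draw each intercept from the integer grid
{−5, …, 5} with seeded Gaussian jitter and jitter the emission block.
The default of 50 starts trades local-optimum risk against runtime and
is the knob to raise for hard problems. One master seed drives
everything; all outputs are reproducible.

After fitting, states are relabelled by ascending fitted mean MD
(state 1 = shallowest). The relabelling permutes the emission blocks and
the transition-coefficient blocks jointly; it is applied only when the
covariate term structure is invariant under the permutation (always true
for `model2` and intercept-only models; for `model1`/`model3`/`model4`
the deepest state's rows are structurally special, so a fit whose state
order disagrees with the term structure keeps its labels and is
flagged). Mixture-sorted starting values make this rare in practice.
Fits whose decoded path gives a state under 1% of dives are flagged as
possibly overfitted.

Confidence intervals are Wald intervals from the inverse observed Fisher
information (numerically differentiated score for the log-normal
families, numerical Hessian otherwise), computed on the working scale
and mapped through the monotone back-transforms; a non-positive-definite
Hessian flags the intervals unavailable without failing the fit.
Model selection uses AIC = −2ℓ + 2·np with `aic_table` producing ΔAIC
rankings; comparisons require identical data (enforced by a data hash).

## Diagnostics

Forecast pseudo-residuals are one-step-ahead probability integral
transforms per coordinate: z_{t,k} = Φ⁻¹(P(X_{t,k} ≤ x_{t,k} | x_1,
…, x_{t−1})), with the forecast distribution mixing the
state-conditional *marginal* CDFs with the predictive state
probabilities from the scaled forward recursion (δ for the first dive).
For the dependent families the univariate marginals are unchanged by the
dependence (log-normal marginals of the trivariate log-normal; gamma
marginals of the copula), so no conditioning on sibling coordinates is
involved. Under a correctly specified model the residuals are exactly
standard normal, which the calibration test exploits (Kolmogorov–Smirnov
at the 1% level on model-simulated records).

Viterbi decoding runs in log space with ties broken to the lowest state
index, making decoding deterministic.

## Preprocessing

Dives are scored from a 1 Hz depth trace by locating surface zeros:
depth ≤ 0.25 m (half the 0.5 m sensor resolution, configurable) counts
as surface. An interval between consecutive surface zeros containing at
least one measurement ≥ 20 m is a dive; MD is the largest measurement in
the interval and DT the time between the delimiting zeros. Intervals not
qualifying as dives (brief sub-threshold submersions) accumulate into
the preceding dive's PD, which runs to the opening zero of the next dive
(to the last surface sample of the record for the final dive). Records
that start or end underwater have the partial dive discarded with a
warning. The pipeline assumes a gap-free trace; dive counts on records
with transmission dropouts may differ from counts produced by other
software.

## Synthetic data

The simulator is a first-class module: it runs the full feedback loop
(covariates computed from the simulated history on a 1 s clock, state
transitions from the origin dive's covariates, emissions from the
state's distribution), so a simulated record passed back through
`compute_covariates` reproduces the simulated covariates exactly — a
tested invariant. Dive t+1 starts when dive t's surface interval ends;
the hour covariate is the wrapped fractional hour of that instant.

`narwhal_like_preset()` is the reference study condition: a 3-state
dependent log-normal configuration whose state-wise response means, SDs
and MD–DT correlations match the published summary table of a fitted
narwhal model (state mean depths 51/174/479 m), obtained by inverting
the log-normal moment map (σ² = log(1 + SD²/E²), μ = log E − σ²/2) and
the correlation conversion. No complete set of published transition
coefficients exists on a reproducible basis (spline knot placements were
not printed), so the preset's transition block is *synthetic*: Model-1
structure, intercepts near −2.3 (state persistence ≈ 0.85, plausible for
bout-structured diving) and smooth covariate effects of magnitude
≲ 1, with τ knots at 0.6/2.8 h and d knots at 1/3 dives (the scales of
the published covariate quantiles). PD is emitted as the state's third
coordinate; no separate surface model.

`render_trace` inverts preprocessing for testing: triangular
descent/ascent reaching MD at mid-dive, 1 Hz sampling, 0.5 m
quantisation, interior samples floored at 0.5 m so quantisation cannot
split a dive. Round trips recover MD within quantisation and DT/PD
within one sample. It makes no attempt at behaviourally realistic dive
shapes (bottom phases, variable rates).

What the generator does *not* emulate: sensor drift and gaps, the 20 m
truncation of real dive records (the preset's state-1 log-normal has
mass below 20 m, as fitted models of truncated data do), serial
dependence beyond the modelled feedback, or between-individual
variability. Passing tests therefore demonstrate internal correctness
and desk-scale statistical behaviour of the estimator under the model,
not field validity.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as
the package's own reference conditions: parameter recovery and residual
calibration use T = 2000 dives from the preset (20 optimisation starts
for the recovery fit); the AIC-direction experiment uses 20 replicates
of T = 400 from a two-state dependent truth; exhaustive-enumeration
checks use m = 2, T = 8. Recovery is assessed on the working scale,
where the Wald quadratic approximation holds, as |estimate − truth| / SE.
Degenerate inputs are handled explicitly: constant covariates give a
degenerate (constant-column) spline basis with a warning; emission
evaluations reject non-positive responses; softmax rows are
overflow-safe; CDF arguments are clipped at 1e-14 before Φ⁻¹.

## Known limitations

* No EM/Baum–Welch, no smoothing probabilities, no bootstrap standard
  errors — estimation is direct numerical ML, matching the approach the
  framework was published with.
* The gamma families rely on finite-difference gradients and are slow
  for m ≥ 3 with rich covariate models.
* ΔAIC values on real data are reproducible only up to optimisation
  noise (multi-start stochasticity), and spline coefficients fitted on
  real records depend on knot placement conventions.
* Hessian-based intervals can be flagged unavailable near boundaries or
  with weakly identified spline coefficients in data-sparse covariate
  regions (the estimates themselves remain valid).
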