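# Methods

## Generative model

The study area is an abstract 50 km × 50 km square split into a 10 × 10
lattice of 5 km grid-squares, grouped 2 × 2 into four 25 km regions (the
only tiling that makes each region a square block of 5 × 5 grids). For a
pollutant metric with overall mean μ and between-grid SD σ_b, one
replicate draws

* grid means μᵢ = μ + eᵢ, eᵢ ~ N(0, σ_b²), redrawn every replicate — the
  grid means are part of the generative model, not fixed nuisance
  parameters;
* a day × grid matrix whose rows are i.i.d. MVN(μ, Ω): no trend,
  seasonality or autocorrelation — days are exchangeable by design, so
  the time-series structure carries no confounding;
* deaths Y_it ~ Poisson(α exp(β x*_it)) with α = 0.32 expected deaths per
  grid-day at zero exposure and β chosen so that a 10 µg/m³ (ozone) or
  10 % (NO₂) increase raises mortality by 0.4 % — β = 0.0003992 per µg/m³
  and β = ln(1.004)/ln(1.10) = 0.0418845 per log-unit respectively.

### Spatial covariance

Between-grid correlation follows a linear distance decay ρ(D) = a + b·D
fitted to standardized between-site monitor correlations (urban ozone:
a = 0.93031, b = −0.00080/km). D is an *effective* distance: the mean
distance between two uniform points, one in each square. Within one 5 km
square this is 2.6 km (closed form 0.52140·side = 2.607; the package
carries a Monte-Carlo oracle for it); between squares it is approximated
by D = d + 2.13/d with d the centre-to-centre distance. The approximation
diverges as d → 0, so the between branch asserts d ≥ 1 km; on the lattice
distinct grids always have d ≥ 5 km.

Ω is the decay correlation matrix times the observed monitor within-site
variance (urban ozone 25.28²), making the common diagonal the implied
*true* within-grid variance (24.36² here, matching the reported 24.35² to
three significant figures) — i.e. the monitor variance purged of
instrument/location error. A linear-in-distance correlation matrix is not
automatically positive semi-definite; if needed, negative eigenvalues are
clipped to a small floor, the matrix reassembled and its diagonal
re-equalised, with a hard error if that moves any correlation by more
than 0.001 (a repair that large would mean the sampled process no longer
follows the stated model). At the default urban-ozone parameters the
matrix is already positive definite (smallest eigenvalue ≈ 1.6 × 10⁻⁴ in
correlation units) and no repair occurs. Sampling uses an
eigendecomposition factor computed once per configuration so singular
(repaired) matrices remain sampleable.

## Error models

* **Monitor**: X = X* + E, ε_it ~ N(0, σ_err²) i.i.d. — pure additive
  classical error. σ_err = 6.77 µg/m³ for urban ozone, derived from the
  decay fit (below).
* **Regional average**: per region, sample l of the 25 grids uniformly
  without replacement and assign the daily mean of their monitor series
  to all 25 grids. Placements are redrawn every replicate, so summaries
  average over monitor siting, matching the placement-averaged theory.
  The averaging mixes Berkson error (spatial smoothing) with classical
  error (σ_err²/l of surviving instrument noise).
* **CTM emulation**: Z = cᵢ + μᵢ + λ(X* − μᵢ) + Δ with
  λ = cov(X*,Z)/var(X*) and Δ ~ N(0, var(Z) − λ²var(X*)). The three
  moments are taken from the observed monitor/CTM comparison (urban
  ozone: cov 455.78, var(Z) 23.41², bias c = 10.25); var(X*) is the Ω
  diagonal. In additive analyses cᵢ = c for all grids (grid fixed effects
  absorb any constant bias); in proportional analyses cᵢ = c + N(0,
  σ_diff²) per grid per replicate, because after back-transformation a
  grid-varying bias is no longer absorbed.
* **Proportional error**: NO₂ is simulated as log_e(NO₂) and
  exponentiated before averaging/regression when the relationship of
  interest is with the untransformed concentration; the stored panels are
  always on the simulation scale with an explicit scale flag (applying
  the back-transform twice is a hard error).

Within a replicate all scenarios share one truth and one mortality panel
— a variance-reduction choice that sharpens scenario contrasts at equal
replicate count without changing any expectation.

## Estimation

The analysis model is log E(Y_it) = aᵢ + β w_it with one intercept per
grid and no global intercept. The intercepts have the closed-form profile
solution aᵢ(β) = log(Σ_t y_it / Σ_t exp(β w_it)), so β is found by Newton
iteration on the 1-D profile likelihood (softmax weights stabilised by
per-grid max subtraction; relative step tolerance 1e-10, max 50
iterations, step damping for poor starts). The Wald SE is the inverse
square root of the profile information, which for this model equals the β
block of the inverted full-model information — the tests verify agreement
with a dummy-variable Poisson GLM to 1e-6 relative in both β̂ and SE.
Grids with all-zero counts have −∞ intercepts, carry no information about
β, and are dropped with a count; exposure constant within every grid is
collinear with the fixed effects and rejected. Coverage uses 95 % Wald
intervals and power the two-sided 5 % Wald test — the conventional GLM
output, and the only choice consistent with summarising by mean SE.
Non-converged fits are excluded from summaries and counted, never
imputed.

## Theory

With fixed effects absorbing constants, the large-sample slope from
regressing on surrogate W is β·cov(X*,W)/var(W) per grid, averaged over
grids. For grid-specific CTM data this is cov(X*,Z)/var(Z) (urban ozone
0.8317 → predicted β̂×10 = 0.00332). For the single-monitor design,
cov(X*_i, X_m) is σ_w² when i = m and ρ(D_im)·σ²_monitor otherwise (the Ω
construction scales off-diagonals by the *monitor* variance), giving

    factor = (σ_w² + (n−1)·ρ̄·σ²_monitor) / (n·(σ_w² + σ_err²)),  n = 25,

with ρ̄ the mean decay correlation over ordered distinct within-region
pairs (0.9195 for urban ozone; factor 0.9203 → 0.00367). A brute-force
check — simulating a 25-grid region at length and linearly regressing
truth on each monitor series — agrees within 1 %. The error variance
var(Z − X*) decomposes exactly as CC + BC with CC = var(Z) − cov(Z,X*)
(classical-like, attenuating) and BC = var(X*) − cov(Z,X*) (Berkson-like,
power-costing).

## Calibration

From paired daily monitor/CTM series per site: per-site statistics over
paired days only, sites with fewer than 364 paired days excluded, site
pairs below 364 overlapping days dropped; cross-site summaries are
unweighted site-level averages per site type. Between-site correlations
use monitor series standardized within site; their decay with straight-
line distance is fitted by OLS (an optional quadratic term is a
diagnostic reported as an R² gain, not part of the generating model). The
instrument/location error SD is derived by reading the decay fit at the
within-square distance D = 2.6 km as the reliability ratio:
σ_err = √((1 − ρ(2.6)) · σ²_monitor). With the published urban-ozone
inputs this yields 6.79 versus the reported 6.77 — the 0.02 discrepancy
(rounded published inputs) is accepted, not hidden; the package uses 6.77
in its presets.

The fixture generator emulates such a network: sites uniform in a square
region (default 600 km, a national-network scale), latent true series MVN
with the decay correlation *inflated* by the reliability ratio so that
the noisy monitor channel reproduces the stated observed decay,
independent per-channel missingness, and a CTM channel from the same
linear projection. It does **not** emulate seasonality, preferential
monitor siting, autocorrelated instrument error or urban/rural parameter
differences (strata share generating parameters) — recovery tests
therefore validate the estimation chain, not robustness to those real-
data features.

## Problem sizes and defaults

Replicates default to 1000 (the acceptance script's choice for the
simulated column); the test suite uses 500 for the shared urban-ozone run
and 300-day-scale panels elsewhere, with tolerances always expressed in
Monte-Carlo SEs computed from the replicates themselves. The day count is
fixed at 1095 (a 3-year series; days are abstract indices, no calendar).
Per-replicate seeds are spawned from the master seed via SeedSequence, so
any replicate is reproducible in isolation and result tables are
byte-identical under a fixed master seed.

## Known limitations

* Only the urban-ozone configuration is fully determined by published
  inputs; rural ozone and both NO₂ metrics need user-supplied decay
  coefficients and σ_err (presets mark them REQUIRED), so their simulated
  columns are machinery, not reproductions.
* The linear decay model extrapolated far beyond the fitted range clamps
  at ±1 (with a warning) and can fail the PSD-repair tolerance — by
  design, since the sampled process would not be the stated one.
* No seasonality, trend, overdispersion, confounders, multi-pollutant
  models, anisotropy or preferential monitor placement; theory covers
  the CTM and single-monitor designs only (no closed form for
  intermediate l or proportional error).
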