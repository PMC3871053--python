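# exposim

Exposure **measurement error** in Poisson time-series analyses of air
pollution and mortality: a simulation laboratory for comparing sparse
monitor networks against gridded chemistry-transport-model (CTM) output.

## The problem

Short-term air-pollution epidemiology regresses daily death counts on
daily pollutant concentrations. The exposure series is never the true
ambient concentration of the 5 km × 5 km grid-square where people live: it
is either an average over the few monitors in the region (instrument and
siting error, spatial averaging) or the output of a chemistry-transport
model (correlated with truth, but biased and noisy). Classical error
(surrogate = truth + noise) attenuates the estimated relative risk toward
the null by the reliability ratio var(X*)/var(Z); Berkson error (truth =
surrogate + noise) mainly costs power. Real surrogates mix both, and the
mix determines how badly the health-effect estimate, its standard error,
confidence-interval coverage and power are degraded.

`exposim` simulates the whole chain on a 50 km × 50 km study area (4
regions of twenty-five 5 km grid-squares):

1. **Truth** — grid means μᵢ ~ N(μ, σ_b²); daily fields are i.i.d. rows of
   MVN(μ, Ω), where Ω = ρ(D) · σ²_monitor and ρ(D) is a linear
   distance-decay correlation evaluated at the effective between/within
   square distance D (D = d + 2.13/d between squares, D = 2.6 km within).
2. **Mortality** — Y_it ~ Poisson(α · exp(β · x*_it)).
3. **Surrogates** — monitor series X = X* + N(0, σ²_err); regional
   averages of *l* ∈ {1,…,25} monitors assigned to every grid of a
   region; a CTM channel emulated by the linear projection
   Z = c + μᵢ + [cov(X*,Z)/var(X*)](X* − μᵢ) + Δ, which pins the bias,
   variance and truth-covariance of real model output; optional
   proportional (log-scale) error with back-transformation.
4. **Re-analysis** — Poisson regression of the counts on each surrogate
   with grid fixed effects (profile-likelihood Newton fit, identical to
   the dummy-variable GLM), repeated over replicates to estimate mean
   β̂, mean SE, 95 % coverage and power.

Closed-form attenuation predictions (cov(X*,Z)/var(Z) for CTM data; a
placement-averaged slope for the single-monitor design), the
classical-like/Berkson-like decomposition CC = var(Z) − cov(Z,X*),
BC = var(X*) − cov(Z,X*), and a calibration module that estimates every
generating parameter from paired monitor/CTM site data (with a synthetic
network fixture generator) complete the pipeline.

## Worked example

Theory first — attenuation factors for urban-background ozone from the
observed monitor/CTM comparison statistics (cov = 455.78, var(Z) = 23.41²,
σ_err = 6.77, monitor variance 25.28², decay 0.93031 − 0.00080·D):

```console
$ exposim theory
scenario,attenuation_factor,predicted_beta,true_beta,rho_bar
ctm,0.831673,0.0003320037,0.0003992,
single_monitor,0.920329,0.0003673953,0.0003992,0.919534
```

Grid-specific CTM data are predicted to attenuate the true coefficient
(β×10 = 0.00399, a 0.4 % mortality increase per 10 µg/m³) to 0.00332
(−17 %); a single monitor per 25 km region only to 0.00367 (−8 %).

The same comparison by simulation (200 replicates of a 3-year, 100-grid
study; `l` = monitors per region):

```python
from exposim.presets import urban_ozone_additive
from exposim.runner import run_experiment

cfg = urban_ozone_additive(n_reps=200, master_seed=7,
                           scenarios=("l=1", "l=10", "true", "ctm"))
print(run_experiment(cfg).format_table(scale10=True))
```

```text
scenario    beta_hat x10   (mean SE)  coverage  power  atten.
l=1              0.00368 (0.00209)       96%    41%      8%
l=10             0.00404 (0.00217)       96%    44%     -1%
true             0.00406 (0.00217)       97%    46%     -2%
ctm              0.00341 (0.00226)       94%    32%     15%
```

Ten monitors per region are essentially unbiased; one monitor loses ~8 %;
CTM-emulated exposure loses ~15 % and a noticeable slice of power —
matching the closed-form predictions above to within Monte-Carlo error.
Coverage stays nominal here because for urban ozone the error is mostly
Berkson-like (`exposim decompose`: CC = 92.2 vs BC = 137.1).

## Layout

| module | contents |
| --- | --- |
| `exposim.geometry` | grid/region layout, effective distances, decay correlation, Ω |
| `exposim.truth` | grid means, MVN daily fields, Poisson mortality |
| `exposim.errors` | monitor error, CTM emulation, regional averages, back-transform |
| `exposim.estimation` | `PoissonFixedEffects` model / results, replicate summaries |
| `exposim.theory` | closed-form attenuation, CC/BC decomposition |
| `exposim.runner`, `exposim.presets` | replicate loop, results tables, shipped configurations |
| `exposim.calibration` | site summaries, decay fits, σ_err, synthetic network fixtures |
| `exposim.cli` | `exposim simulate / theory / decompose / calibrate / fixtures` |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
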