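# Methods

This note records the statistical model, its assumptions, every default the
package fixes, what the synthetic-data generator emulates, the numerical
choices inside the sampler, and the known limitations. Nothing here is an
empirical claim about real populations; all quantitative statements about
estimator behaviour refer to the package's own test suite.

## 1. Data and design

A search-encounter survey produces three raw inputs:

1. **GPS tracks** — timestamped fixes per searcher (planar km coordinates);
2. **sightings** — verified records of identified individuals (id, sex,
   location, date);
3. **habitat mask** — an ESRI ASCII grid marking pixels unsuitable as
   activity-centre locations.

The searched area is discretized into **trap pixels** (default 1 km side).
A trap is *active* on an occasion (one calendar day) if any searcher drove
through it that day; `EFFORT_jk` is the km driven in pixel *j* on day *k*.
Each inter-fix segment is assigned to the pixel containing its midpoint on
the occasion of its start time; segments spanning midnight are split at the
day boundary by linear interpolation in time. With fixes seconds apart the
midpoint rule is indistinguishable from exact polyline clipping.

The **state space** extends the searched extent by a buffer (activity
centres can lie outside the searched area) and is discretized into pixels of
0.65 km side by default, with unsuitable pixels removed. The buffer should
comfortably exceed the largest movement scale; the mean maximum distance
moved (MMDM, computed by `searchscr.mmdm`) is the design summary used to
judge that.

Detections are binarized: individual × trap × occasion, with repeated
same-pixel-same-day sightings collapsed (the model is Bernoulli per cell).
A detection in a cell with no recorded effort (e.g. an opportunistic report)
receives an imputed effort floor of **0.1 km** so the cell is active; the
event is logged.

## 2. Probability model

For individual *i*, trap *j*, occasion *k*:

```
π_ijk = 1 − exp(−exp(η_ijk))                        (cloglog link)
η_ijk = log λ0 + β_eff log EFFORT_jk + β_sex SEX_i − f(d_ij)
f(d)  = (d / σ_SEX_i)^(2θ)
```

π = 0 where effort = 0. The cloglog link makes the per-cell probability a
hazard accumulation, so a cell's survival probability factorizes as
`exp(−μ)` with `μ = exp(η)` — the property the sampler exploits.

`f(d) = (d/σ)^(2θ)` is the package's parameterization of the
exponential-to-Gaussian continuum: `exp(−f)` is negative-exponential in *d*
at θ = 0.5 and Gaussian at θ = 1, with σ in km at every θ. The two limit
shapes pin the family only up to a rescaling of σ; this choice is recorded
in run metadata (`metadata["kernel"]`) so fits remain comparable.

**Augmentation.** The *n* detected individuals are padded to *M* rows
(`default_m_total(n) = 4n`, chosen so the inclusion probability ψ typically
stays inside (0.2, 0.8); the sampler warns when its posterior mean leaves
that range — remedy: change *M*). Then

* `z_i ~ Bernoulli(ψ)`, `N_super = Σ z_i ~ Binomial(M, ψ)` given ψ;
* `SEX_i ~ Bernoulli(ψ_sex)` (0 = female, 1 = male), observed for detected
  individuals, latent otherwise;
* `s_i` uniform over suitable state-space pixels;
* density `D = 100 · N_super / suitable area` (per 100 km²), and the derived
  sex ratio is `(1 − ψ_sex)/ψ_sex` females per male.

**Priors** (over the sampling coordinates): flat on `log λ0`, flat on
β_eff and β_sex, flat on σ_F, σ_M up to an upper bound at the state-space
diagonal, Uniform(0.5, 1) on θ, Beta(1, 1) on ψ and ψ_sex. The σ bound
exists because with no included individuals of one sex that σ's likelihood
is flat and a fully flat prior gives an improper posterior (observed in
testing as an unbounded random-walk drift); the bound is inactive whenever
the data constrain σ.

**Variants.** Model 1: β_sex and θ free. Model 2: β_sex = 0. Model 3:
β_sex = 0, θ fixed. Model 4: θ fixed. θ's fixed value defaults to 0.75
(the centre of its support, used when the data cannot separate the shape
from the scale). σ stays sex-specific in every variant: it is a movement
parameter, not merely a detection one.

## 3. Sampler

Metropolis–Hastings-within-Gibbs, per iteration:

1. **Detection parameters** — one-at-a-time random walks on transformed
   scales (log for λ0 and σ, identity for the βs, rescaled logit for θ)
   with the appropriate prior/Jacobian increments. Proposal scales default
   to {λ0: 0.25, β_eff: 0.05, β_sex: 0.3, σ: 0.15, θ: 0.5} and adapt toward
   35% acceptance **during burn-in only**, so retained draws come from a
   fixed kernel (detailed balance preserved).
2. **Activity centres** — for each individual, a uniform proposal over the
   suitable pixels inside a (2h+1)² pixel window around the current pixel;
   the Hastings ratio includes the window-count ratio because suitable-pixel
   counts differ between locations. The half-width h adapts in burn-in
   toward a 20–60% acceptance band.
3. **z** — exact Gibbs: `Pr(z=1|·) = ψq / (ψq + 1 − ψ)` with `q = exp(−hazard)`
   the probability of an all-zero history.
4. **sex** — Gibbs for latent sexes (log-odds form to avoid underflow when
   hazards are large), then `ψ_sex ~ Beta(1 + males, 1 + females)` counted
   over included individuals.
5. **ψ** — `Beta(1 + Σz, 1 + M − Σz)`.

Likelihood evaluations use the hazard factorization: for individual *i* the
all-miss part is `−a_i Σ_j w_ij C_j` with `w = exp(−f)`,
`C_j = Σ_k EFFORT_jk^β_eff` over active occasions, and
`a_i = λ0 exp(β_sex SEX_i)`; detection cells add `log(1 − exp(−μ)) + μ`.
The sampler caches the log-distance matrix, kernel matrix and effort sums,
and each parameter proposal recomputes only the rows it touches. A
reference `complete_data_loglik` implementation exists independently in
`searchscr.model` and the two are pinned together by oracle tests (50
random instances at 1e-10, plus property-based instances).

**Chains and seeds.** Defaults: 8 chains × 11,000 iterations, 1,000
burn-in, thinning 2 (5,000 retained per chain). Chain RNGs derive from
`SeedSequence(seed).spawn(chains)`; identical seeds give bit-identical
draws.

**Initialization.** λ0 = detections/total effort; σ per sex = MMDM/2
(floor 0.5 km); ψ = n/M (clipped); ψ_sex = observed proportion male;
detected individuals start at the nearest suitable pixel to their sighting
centroid; augmented ones uniform.

## 4. Diagnostics

* **PSRF** — the classic Gelman–Rubin statistic
  `sqrt(((L−1)/L · W + B/L)/W)` over chains, floored at 1.0 (finite-sample
  noise can push the raw estimator below 1, which carries no information).
  Convergence threshold: max PSRF over free parameters and N_super < 1.2.
* **Posterior predictive p-value** — Freeman–Tukey discrepancy
  `T = Σ_i (√y_i· − √e_i·)²` on per-individual detection totals over
  included individuals, compared with replicate data simulated from the same
  draws; computed over a random subsample of ≤ 200 retained draws (the
  statistic stabilizes well before that; the subsample keeps the check
  cheap). Adequacy band: (0.15, 0.85).
* **Density surface** — posterior mean count of included activity centres
  per pixel divided by pixel area; integrates exactly back to the posterior
  mean of N_super.

Calibration of both diagnostics is exercised by the acceptance suite:
stationary synthetic chains give PSRF in [1, 1.05], and across 20 correctly
specified replicate fits the p-value stays inside the band in ≥ 16.

## 5. Synthetic-data generator

`simulate_survey(scenario, seed)` is a pure function of its arguments and
emulates the field design end to end:

* **habitat mask** — a clustered random field (sum of Gaussian bumps)
  thresholded at the exact quantile giving `round(frac_unsuitable · n_pixels)`
  unsuitable pixels. `mask_avoid_search_core` places the bumps outside the
  searched core, for surveys where the unsuitable land (settlement/agriculture
  fringe) surrounds a protected searched area rather than interleaving it;
* **tracks** — correlated random walks (fixed step = fix spacing, default
  10 s fixes at 0.1 km) reflecting off the searched rectangle, optionally
  biased toward a hotspot to concentrate effort; one track per searcher-day,
  assigned round-robin to occasions;
* **population** — activity centres uniform over suitable pixels, sexes
  Bernoulli(`psi_sex_true`);
* **encounters** — Bernoulli draws from exactly the fitted cloglog model
  over the rasterized effort, collapsed to sightings at trap centroids.

Two configurations ship with the package:

* **`ScenarioConfig()` defaults** — a 20 × 20 km searched area with an 8 km
  buffer, N = 40, K = 30 occasions, σ_F = 2.7 km, σ_M = 5.4 km (deliberately
  2× apart), λ0 = 0.01, 90 searcher-days of 60 km. This is the scaled-down
  recovery scenario used by the acceptance tests: 20 replicate Model-1 fits
  must cover the true density with their 95% interval in ≥ 18/20 and recover
  σ_M > σ_F.
* **`mara_like` bundled scenario** — a large-survey configuration (49 × 49 km
  core, 40 km buffer, 0.65 km state pixels, ~43% unsuitable, 92 occasions,
  ~8,400 km of effort, ψ_sex = 0.162, σ_F = 3.66 km, σ_M = 8.13 km,
  θ = 0.83, β_sex = −0.12). The walk parameters (λ0 = 0.005, turn_sd = 0.1,
  hotspot_bias = 0.005, 91.3 km/searcher-day) were calibrated once so the
  generator reproduces the *observed-data scale* of the surveys this design
  emulates (~25 detected individuals, ~55 sightings) and then frozen; they
  were never adjusted against test outcomes.

## 6. Numerical choices

* Kernel evaluated as `exp(−exp(2θ(log d − log σ)))` from a cached
  log-distance matrix — one transcendental per entry instead of a `power`
  call, and numerically identical to the direct form.
* `log(1 − π) = −μ` is used exactly (cloglog identity), avoiding
  catastrophic cancellation for small μ; `log π = log(−expm1(−μ))`.
* Sex full-conditional computed in log-odds to avoid `0/0` when both sexes'
  survival probabilities underflow.
* Thinning (default 2) exists purely to halve memory for the latent traces
  (chains × draws × M integers for s, z, sex); it discards no information
  the summaries need.
* Grid dimension counts use `ceil((extent)/side − 1e-9)` so float noise
  cannot add a spurious pixel row/column.
* Serialized draws (`write_draws`/`read_draws`) round-trip parameters and
  derived quantities but deliberately not the latent traces (they are large
  and only needed for the predictive check and density surface, both
  computed at fit time).

## 7. Limitations

* Coordinates must already be planar km; no projection handling is included.
* Closure is assumed over the survey window (no birth/death/migration);
  occasions are calendar days.
* The effort covariate is km driven; detectability differences between
  habitat types or daylight conditions are not modelled.
* Activity centres are static points; transients or drifting home ranges
  violate the model.
* The Bernoulli-per-cell observation model collapses repeat same-cell
  same-day sightings, losing any information in within-day encounter counts.
* With very few detected individuals of one sex, that sex's σ is informed
  mostly by the prior bound and the augmented all-zero histories; estimates
  should be read accordingly.
* The predictive check targets per-individual detection totals only; other
  discrepancies (spatial clustering of misfits, per-occasion totals) are not
  checked.
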