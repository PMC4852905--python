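# searchscr

Bayesian sex-specific spatially explicit capture–recapture (SECR) for
**unstructured search-encounter surveys** — density estimation from GPS
search tracks and verified sightings of individually identifiable animals,
without a fixed detector array.

## The scientific problem

Large carnivores with individually distinctive coat patterns (cheetahs,
leopards, wild dogs…) are often surveyed by *searching*: teams drive through
an area, photograph every animal encountered, and identify individuals from
their markings. Unlike camera-trap studies there are no fixed detectors, so
standard SECR software does not apply directly. The search-encounter design
solves this by discretizing the landscape into pixels and treating each
pixel as a "trap" that is active on any day a searcher drove through it,
with the kilometres driven in the pixel that day as an observation-level
covariate. Density then comes from a spatial capture–recapture model with
data augmentation, fitted by MCMC.

Sex matters: in many carnivores males range much more widely than females.
Ignoring that heterogeneity biases density estimates, so the model carries
sex-specific movement scales and a (latent, for undetected animals) sex for
every individual.

## The model

Detection of individual *i* in trap pixel *j* on occasion (day) *k* is
Bernoulli with a complementary log-log link:

```
cloglog(π_ijk) = log(λ0) + β_eff · log(EFFORT_jk) + β_sex · SEX_i
                 − f(d_ij; θ, σ_SEX_i)
f(d) = (d / σ)^(2θ)
```

* `λ0` — basal encounter rate at distance 0 and 1 km of effort;
* `EFFORT_jk` — km driven in pixel *j* on day *k* (π = 0 where effort = 0);
* `d_ij` — distance from the animal's latent activity centre `s_i` to the
  pixel centroid;
* `σ_F`, `σ_M` — sex-specific movement/detection-decline scales (km);
* `θ ∈ [0.5, 1]` — detection shape: `exp(−f)` is negative-exponential in
  distance at θ = 0.5 and Gaussian (half-normal) at θ = 1.

Population size uses data augmentation: the *n* detected individuals are
padded with all-zero capture histories to a cap *M*; each individual has an
inclusion indicator `z_i ~ Bernoulli(ψ)`, a sex `SEX_i ~ Bernoulli(ψ_sex)`
and an activity centre uniform over the *suitable* pixels of a buffered,
habitat-masked state space. Abundance is `N_super = Σ z_i` and density is
`D = 100 · N_super / suitable area` (animals per 100 km²).

Four model variants are supported: β_sex free/fixed-at-0 × θ free/fixed.
Fitting is Metropolis–Hastings-within-Gibbs (random-walk updates for the
detection parameters, discrete pixel-window proposals for activity centres,
conjugate Beta draws for ψ and ψ_sex). Diagnostics: multi-chain
Gelman–Rubin PSRF and a Freeman–Tukey posterior predictive p-value on
per-individual detection counts.

## Worked example

```python
from searchscr import (SamplerConfig, ScenarioConfig, fit_synthetic,
                       simulate_survey)

survey = simulate_survey(ScenarioConfig(), seed=7)
config = SamplerConfig(iterations=4_000, burn_in=1_000, thin=2, chains=2,
                       seed=1)
result = fit_synthetic(survey, variant=1, config=config, m_total=120)
print(result.report.summary.round(3))
```

Output (from `python examples/02_fit_and_diagnose.py`):

```
Model 1 [beta_sex, theta(.)]
             mean      sd
parameter
lam0        0.013   0.008
beta_eff   -0.037   0.148
beta_sex   -0.108   0.695
sigma_f     2.430   0.890
sigma_m     5.735   0.921
theta       0.849   0.110
psi         0.525   0.148
psi_sex     0.416   0.125
nsuper     62.989  17.206
density     5.942   1.623
sex_ratio   1.653   0.901

max PSRF        : 1.018 (converged: True)
Bayesian p-value: 0.515 (adequate: True)
density         : 5.94 [3.40, 9.72] / 100 km^2 (truth 3.77)
surface total   : 63.0 animals (peak pixel 0.401 / km^2)
```

The simulated truth (3.77 animals / 100 km², σ_M = 2 σ_F) falls inside the
95% credible interval, and the sex-specific movement scales are recovered in
the right order. `examples/` contains three narrative scripts: simulating a
survey, fitting + diagnosing, and comparing the four model variants.

## Command line

The same pipeline is scriptable from a shell:

```bash
searchscr simulate --out runs/demo --seed 7          # tracks, sightings, mask
searchscr fit      --config runs/demo/run.yaml       # MCMC fit -> draws, summary
searchscr diagnose --draws runs/demo/fit/draws       # PSRF + posterior table
searchscr report   --fits runs/demo/fit              # side-by-side comparison
```

`simulate` without `--scenario` uses the bundled `mara_like` scenario: a
large-survey configuration (49 × 49 km searched core, 40 km buffer, ~43%
unsuitable habitat, 92 daily occasions, ~8,400 km of effort, strongly
female-biased sex ratio, σ_M ≫ σ_F) that exercises the code at realistic
scale.

## Layout

```
src/searchscr/    library: grids, rasters, effort, encounters, model,
                  sampler, diagnostics, simulate, io, pipeline, cli
examples/         narrative scripts (simulate / fit / compare variants)
tests/            unit, property-based and acceptance suites
scripts/          acceptance.py end-to-end reproduction script
docs/methods.md   model, assumptions, numerical choices, limitations
```
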