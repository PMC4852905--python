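# Mara-like synthetic survey: the default end-to-end fixture.
# Scale and truth values mirror the published survey conditions this package
# emulates: a ~2,400 km^2 searched area inside a 40 km-buffered state space,
# ~43% unsuitable habitat, 92 daily occasions, ~8,400 km of patchy effort,
# female-biased sex ratio and sex-specific movement scales.
search_extent: [0.0, 0.0, 49.0, 49.0]
buffer_km: 40.0
state_pixel_km: 0.65
trap_pixel_km: 1.0
frac_unsuitable: 0.4258
mask_bumps: 40
mask_avoid_search_core: true
n_true: 150
psi_sex_true: 0.162
lam0: 0.005
beta_eff: 0.0
beta_sex: -0.12
sigma_f: 3.66
sigma_m: 8.13
theta: 0.83
k_occasions: 92
n_searcher_days: 92
daily_km: 91.3
fix_spacing_km: 0.1
turn_sd: 0.1
hotspot_bias: 0.005
hotspot_xy: null
start_date: "2014-08-01"
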