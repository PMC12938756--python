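cohort:
  acquisition_s: 300.0
  bin_width_ps: 10.0
  counts_per_wavelength: 1000000.0
  incident_photons: 1000000000000.0
  intensity_factor_mean: 1.3
  intensity_factor_sd: 0.1
  irf_fwhm_ps: 150.0
  irf_t0_ps: 300.0
  lateral_rho_mm: null
  mus_midline_mean: 0.9
  mus_midline_sd: 0.1
  n_bins: 1000
  n_segments: 10
  n_subjects: 30
  n_tissue: 1.4
  param_noise_counts: 0.001
  param_noise_mu_a: 0.02
  param_noise_mus: 0.01
  param_noise_path: 0.005
  poisson_noise: true
  rho_mm: 30.0
  sco2_mean_pct: 65.0
  sco2_sd_pct: 5.0
  seed: null
  site_factor_mean: 0.9
  site_factor_sd: 0.03
  total_hb_mean_uM: 45.0
  total_hb_sd_uM: 8.0
  venous_thb_mean_g_dl: 15.0
  venous_thb_sd_g_dl: 2.0
  water_fraction: 0.9
  wavelengths:
  - 762.0
  - 801.0
  - 836.0
fit:
  d_convention: scatter
  ftol: 1.0e-12
  gtol: 1.0e-12
  max_nfev: 400
  min_total_counts: 10000.0
  min_window_bins: 20
  mu_a_bounds:
  - 0.0001
  - 1.0
  mu_s_prime_bounds:
  - 0.05
  - 5.0
  n_restarts: 3
  reweight_passes: 1
  rise_fraction: 0.01
  smooth_bins: 5
  t_shift_bounds_ps:
  - -200.0
  - 200.0
  tail_fraction: 0.001
  xtol: 1.0e-12
statistics:
  alpha: 0.05
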