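# Default configuration for the hotrocks pipeline.
#
# Every block can be overridden by a user YAML file passed to
# hotrocks.config.load_config(); user keys are deep-merged over these.

rock_field:
  n_miz: 12
  n_hiz: 12
  # intertidal elevation (m above MLLW) ranges and target per-zone means
  miz_elevation_range: [-0.32, 0.23]
  miz_elevation_mean: 0.0
  hiz_elevation_range: [0.31, 1.10]
  hiz_elevation_mean: 0.8
  surface_area_range_cm2: [568.0, 2671.0]
  volume_range_cm3: [5162.0, 50472.0]

tide:
  # generic mixed semidiurnal harmonic model: (amplitude m, period h, phase rad)
  mean_level_m: 0.93
  constituents:
    - [0.55, 12.4206012, 0.0]
    - [0.37, 23.9344697, 1.1]
    - [0.23, 25.8193417, 2.3]
    - [0.15, 12.0, 0.7]
  offset_correction:
    time_shift_h: 0.0
    height_shift_m: 0.0

microclimate:
  sampling_interval_min: 30
  water:
    mean_c: 12.55            # annual-mean water temperature
    seasonal_amplitude_c: 0.45
    seasonal_peak_doy: 240   # late August
    diurnal_amplitude_c: 0.40
    ar_phi: 0.95             # AR(1) coefficient per 30-min step
    ar_sd: 0.55              # stationary SD of the AR(1) anomaly
  air:
    # per-zone air-excursion parameters for emersed records
    MIZ:
      day_amplitude_c: 4.0
      night_amplitude_c: 1.5
      seasonal_mod_day: 0.5
      seasonal_mod_night: 0.5
      rock_sd: 0.08          # among-rock multiplicative heterogeneity
      weather_sd_c: 1.0      # shared day-to-day weather noise (daytime)
      noise_sd_c: 0.25       # within-day record noise
      tau_hours: 1.5         # Newtonian relaxation time constant
      elevation_coef_per_m: 0.0
      elevation_ref_m: 0.0
      day_sharpness: 1.0
    HIZ:
      day_amplitude_c: 5.2
      night_amplitude_c: 1.45
      seasonal_mod_day: 0.9
      seasonal_mod_night: 0.5
      rock_sd: 0.05
      weather_sd_c: 4.0
      noise_sd_c: 0.25
      tau_hours: 1.2
      elevation_coef_per_m: 1.2  # excursions grow with height on shore
      elevation_ref_m: 0.8       # zone mean elevation
      day_sharpness: 2.0         # midday-peaked heating
  quantize_half_degree: false
  exclusion_windows: []      # e.g. [["2016-02-01", "2016-04-03"]]

traits:
  ctmax:
    intercept_c: 33.0
    slope_c_per_mm: -0.14
    residual_sd_c: 1.5
  tesc:
    intercept_c: 35.12
    slope_c_per_mm: -0.88
    residual_sd_c: 2.0
  tpref_c: 15.0
  mean_ctmax_c: 30.5   # population mean heat tolerance (null model, censoring)
  mean_tesc_c: 20.5    # population mean escape temperature (null model)

metabolism:
  censor_threshold_c: 30.5
  masses_g:
    small: 0.9
    large: 4.3
  # log10(whole-animal rate, uL O2/h) = a + b * T(C). Calibration set:
  # Q10 = 2 in both media; water rates anchored to ~20 (large) and ~4
  # (small) uL O2/h near the 13 C holding temperature; air rates depressed
  # relative to water, more strongly for large crabs.
  coefficients:
    small:
      water: {a: 0.2107, b: 0.030103}
      air: {a: 0.1138, b: 0.030103}
    large:
      water: {a: 0.9097, b: 0.030103}
      air: {a: 0.6878, b: 0.030103}

ibm:
  n_crabs: 1000
  n_cols: 100
  n_rows: 20
  p_move: 0.8
  p_die: 0.8
  n_reps: 50
  n_days: null             # null = every day covered by the pools
  max_moves_per_day: 50
  null_model: false
  cw_range_mm: [4.0, 21.0]
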