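# Default calibration for the synthetic chough foraging study.
#
# Stratum means (stay times in seconds, flock sizes in birds) encode the
# study's reported group averages; variance, dispersion and spatial
# parameters are generator choices documented in docs/methods.md.

stay_mean_s:
  red_billed:
    2021: {monospecific: 473.0, mixed: 146.0}
    2022: {monospecific: 176.0, mixed: 176.0}
  yellow_billed:
    2021: {monospecific: 210.0, mixed: 210.0}
    2022: {monospecific: 134.0, mixed: 134.0}
stay_log_sd: 0.6
stay_flock_slope: -0.1
day_intercept_sd: 0.3
obs_per_stratum: 200

flock_mean:
  yellow_billed: {2021: 28.8, 2022: 18.7}
  red_billed: {2021: 6.7, 2022: 8.0}
flock_dispersion: 5.0
mixed_flock_prob: 0.15
flocks_per_stratum: 100

spatial_centres:
  yellow_billed: {x_m: 0.0, y_m: 0.0, spread_m: 600.0}
  red_billed: {x_m: 800.0, y_m: 500.0, spread_m: 600.0}
  mixed: {x_m: 400.0, y_m: 250.0, spread_m: 300.0}

altitude_range_m:
  yellow_billed:
    2021: [2200.0, 2600.0]
    2022: [2200.0, 2800.0]
  red_billed:
    2021: [2200.0, 2600.0]
    2022: [2200.0, 2600.0]

temp_month_mean_c:
  2021: {1: -5.0, 2: -5.0, 3: -2.0, 4: 1.0, 5: 6.0, 6: 10.0, 7: 13.0, 8: 13.0, 9: 9.0}
  2022: {1: -3.0, 2: -3.0, 3: 0.0, 4: 3.0, 5: 8.0, 6: 12.0, 7: 15.5, 8: 15.5, 9: 11.0}
temp_ar: [0.6, 0.2]
temp_innov_sd: 1.5

precip_zero_prob:
  2021: {1: 0.60, 2: 0.60, 3: 0.60, 4: 0.55, 5: 0.50, 6: 0.50, 7: 0.55, 8: 0.55, 9: 0.55}
  2022: {1: 0.88, 2: 0.88, 3: 0.88, 4: 0.60, 5: 0.55, 6: 0.55, 7: 0.60, 8: 0.60, 9: 0.60}
precip_gamma_shape: 0.9
precip_gamma_mean_mm:
  2021: {1: 8.0, 2: 8.0, 3: 9.0, 4: 10.0, 5: 12.0, 6: 12.0, 7: 11.0, 8: 11.0, 9: 10.0}
  2022: {1: 5.0, 2: 5.0, 3: 6.0, 4: 9.0, 5: 11.0, 6: 11.0, 7: 10.0, 8: 10.0, 9: 9.0}
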