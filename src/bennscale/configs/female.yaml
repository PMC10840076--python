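n: 10000
sex: F
height_mean_cm: 162.0
height_sd_cm: 6.3
age_mean_y: 56.3
age_sd_y: 8.0
age_min_y: 40.0
age_max_y: 70.0
p_true: 1.4
weight_scale: 35.69807830006263
weight_log_sd: 0.18595009143406646
age_weight_slope: 0.002
bf_mean_pct: 36.6
bf_sd_pct: 4.706257985713768
bf_age_slope: 0.1
bf_weight_resid_slope: 5.0
wc_intercept_cm: 57.800000000000004
wc_fm_slope: 1.0
wc_sd_cm: 7.3647810558087885
hip_intercept_cm: 81.48
hip_fm_slope: 0.8
hip_sd_cm: 6.387769563783592
rsh_mean: 0.525
rsh_sd: 0.01276
townsend_mean: -1.35
townsend_sd: 3.0
baseline_hazard: 0.0011
log_hr_age: 0.085
log_hr_index: 0.1
admin_censor_y: 12.0
seed: 0
categorical_freqs:
  ethnicity:
    white: 0.943
    asian: 0.02
    black: 0.017
    other: 0.016
    unknown: 0.004
  alcohol:
    current: 0.903
    never: 0.058
    previous: 0.036
    unknown: 0.002
  smoking:
    current: 0.089
    never: 0.593
    previous: 0.313
    unknown: 0.005
  education:
    less_than_secondary: 0.168
    secondary: 0.193
    vocational: 0.058
    higher: 0.254
    unknown: 0.309
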