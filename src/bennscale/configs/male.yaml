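n: 10000
sex: M
height_mean_cm: 176.0
height_sd_cm: 6.8
age_mean_y: 56.7
age_sd_y: 8.2
age_min_y: 40.0
age_max_y: 70.0
p_true: 1.8
weight_scale: 30.712715425523808
weight_log_sd: 0.14789821667374423
age_weight_slope: 0.002
bf_mean_pct: 25.3
bf_sd_pct: 4.002528424280673
bf_age_slope: 0.1
bf_weight_resid_slope: 4.0
wc_intercept_cm: 74.7
wc_fm_slope: 1.0
wc_sd_cm: 7.62889244910426
hip_intercept_cm: 89.62
hip_fm_slope: 0.6
hip_sd_cm: 5.660706669665901
rsh_mean: 0.522
rsh_sd: 0.0128
townsend_mean: -1.28
townsend_sd: 3.1
baseline_hazard: 0.0019
log_hr_age: 0.085
log_hr_index: 0.1
admin_censor_y: 12.0
seed: 0
categorical_freqs:
  ethnicity:
    white: 0.942
    asian: 0.025
    black: 0.015
    other: 0.013
    unknown: 0.005
  alcohol:
    current: 0.936
    never: 0.027
    previous: 0.034
    unknown: 0.003
  smoking:
    current: 0.123
    never: 0.489
    previous: 0.383
    unknown: 0.005
  education:
    less_than_secondary: 0.17
    secondary: 0.135
    vocational: 0.05
    higher: 0.29
    unknown: 0.336
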