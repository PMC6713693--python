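n_subjects: 16
visit_times:
- 0.0
- 0.0
- 0.0
- 3.0
- 6.0
- 12.0
- 24.0
kinetics:
  lf_percent:
    a: 2.3328
    b: -0.2084
    a1: 0.0417
    sd_a: 0.665
    sd_b: 0.09
    sd_a1: 0.0104
    within_cv: 0.22
  tlv:
    a: 7.4392
    b: -0.0839
    a1: 48.5448
    sd_a: 0.202
    sd_b: 0.02
    sd_a1: 12.136
    within_cv: 0.09
  vat:
    a: 1.5025
    b: -0.0989
    a1: 0.0492
    sd_a: 0.42
    sd_b: 0.03
    sd_a1: 0.0123
    within_cv: 0.1
  sat:
    a: 2.9518
    b: -0.0999
    a1: 0.2787
    sd_a: 0.216
    sd_b: 0.02
    sd_a1: 0.0697
    within_cv: 0.07
rho_decay: 0.5
blood_links:
  glucose:
    predictor: lf_percent
    slope: 0.004
    intercept: 5.248
    resid_sd: 0.57
    subject_sd: 0.57
  insulin:
    predictor: lf_percent
    slope: 0.299
    intercept: 3.443
    resid_sd: 1.97
    subject_sd: 1.97
  total_chol:
    predictor: lf_percent
    slope: 0.066
    intercept: 3.749
    resid_sd: 0.35
    subject_sd: 0.35
  hdl:
    predictor: lf_percent
    slope: -0.004
    intercept: 1.352
    resid_sd: 0.28
    subject_sd: 0.28
  ldl:
    predictor: lf_percent
    slope: 0.07
    intercept: 1.997
    resid_sd: 0.31
    subject_sd: 0.31
  triglycerides:
    predictor: lf_percent
    slope: 0.027
    intercept: 1.152
    resid_sd: 0.83
    subject_sd: 0.83
blood_missing_months:
  glucose:
  - 24.0
  insulin:
  - 24.0
  total_chol:
  - 3.0
  hdl:
  - 3.0
  ldl:
  - 3.0
  triglycerides:
  - 3.0
bmi:
  baseline_mean: 40.6
  between_sd: 4.0
  shape_months:
  - 0.0
  - 3.0
  - 6.0
  - 12.0
  - 24.0
  shape_values:
  - 1.0
  - 0.8275862068965517
  - 0.7167487684729064
  - 0.6773399014778325
  - 0.6748768472906403
  within_cv: 0.005
truncate_rebound: true
rng_seed: 0
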