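# Two-cohort synthetic study at roughly the scale of the real one:
# 36 years, a 45-day spring window, a few hundred birds a spring.
# The early cohort's timing responds to EARLY, the late cohort's to LATE
# (2 days later per +1 SD of the covariate).
n_years: 36
start_year: 1982
season_total_mean: 250
recapture_fraction: 0.1
low_count_years:
  1993: 12
  2011: 20
seed: 4
cohorts:
  - weight: 0.5
    base_mean_day: 14.0
    sd_days: 5.0
    effects: {EARLY: 2.0}
  - weight: 0.5
    base_mean_day: 30.0
    sd_days: 5.0
    effects: {LATE: 2.0}
climate:
  EARLY: {mean: 0.0, sd: 1.0}
  LATE: {mean: 0.0, sd: 1.0}
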