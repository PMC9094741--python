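# Default cohort presets.
#
# athletes  : master athletes cohort (estimated PWV only)
# agbresa   : bedrest-study baseline cohort (estimated + transit-time PWV)
# single_subject : one fixed man in his 50s for the entered-age experiment
#
# Demographics are the published cohort summaries; age_range doubles as the
# truncation interval of the age distribution (the underlying location is
# shifted so the truncated mean equals age_mean).
athletes:
  n: 129
  age_mean: 56.0
  age_sd: 11.0
  age_range: [35.0, 86.0]
  sbp_mean: 128.0
  sbp_sd: 15.0
  dbp_mean: 78.0
  dbp_sd: 8.0
  bmi_mean: 24.0
  bmi_sd: 3.5
  sex_ratio: 0.682
  hr_mean: 61.0
  hr_sd: 11.0
  measure_transit: false

agbresa:
  n: 24
  age_mean: 33.0
  age_sd: 9.0
  age_range: [24.0, 55.0]
  sbp_mean: 125.0
  sbp_sd: 11.0
  dbp_mean: 70.0
  dbp_sd: 7.0
  bmi_mean: 24.3
  bmi_sd: 2.1
  sex_ratio: 0.667
  hr_mean: 62.0
  hr_sd: 9.0
  measure_transit: true

single_subject:
  n: 1
  age_mean: 55.0
  age_sd: 0.0
  age_range: [54.0, 56.0]
  sbp_mean: 120.0
  sbp_sd: 0.0
  dbp_mean: 75.0
  dbp_sd: 0.0
  bmi_mean: 24.0
  bmi_sd: 0.0
  sex_ratio: 1.0
  hr_mean: 60.0
  hr_sd: 0.0
  map_sigma: 0.0
  measure_transit: true
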