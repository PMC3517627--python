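# Shipped default run configuration.
#
# Medication effect magnitudes (broncho_beta, gamma_mult, sens_mult) are
# conventional-magnitude starting values for the population-level
# treatment-effect tuning procedure
# (asthmasim.calibrate.calibrate_treatment_effects); the full pipeline
# calibrates patients under these values and then tunes them against the
# observed-prescribing/perfect-adherence outcome column.  Durations of
# action and dosing schedules are conventional.

master_seed: 0
horizon_days: 365
output_dir: results
scenarios: [OO, OP, EO, EP]

medications:
  SABA:
    broncho_beta: 0.40
    duration: 4.0
    schedule: 0
  LABA:
    broncho_beta: 0.25
    duration: 12.0
    schedule: 2
  ICS:
    gamma_mult: 2.0
    sens_mult: 0.60
    duration: 24.0
    schedule: 2
  OCS:
    gamma_mult: 3.0
    sens_mult: 0.50
    duration: 24.0
    schedule: 1

hospital:
  p_admit: 0.268        # fitted from the baseline hospitalization/ED ratio
  los_mean: 3.0         # mean inpatient stay, days (geometric on whole days)

behavior:
  ocs_after_md: true    # oral-steroid course after an unscheduled visit
  ocs_after_ed: true    # ... and after an ED discharge
  ocs_course_days: 5
  collect_log: true
  initial_condition: stationary

calibration:
  budget: 500
  replicate_years: 3.0
  tolerance: 0.2
  weights: {md: 1.0, ed: 1.0, hosp: 1.0, reliever: 0.5}
  floors: {md: 0.5, ed: 0.5, hosp: 0.5, reliever: 0.25}
  priors:
    lam: [0.0005, 8.0]
    mean_alpha: [0.01, 3.0]
    gamma: [0.01, 2.5]
    q_relief: [0.70, 0.93]
    q_md: [0.45, 0.75]
    q_ed: [0.25, 0.60]

population:
  n: 4930
  adult_fraction: 0.830120
  qualify_pct: 27.1
  fev1_l_mean: 2.71
  fev1_l_sd: 0.71
  adherence_concentration: 10.0
  adult:
    male_pct: 63.8
    age_mean: 43.4
    age_sd: 16.2
    age_range: [18.0, 90.0]
    smoker_pct: 20.25
    fev1_pct_pred_mean: 80.4
    fev1_pct_pred_sd: 14.5
    ics_pct: 42.5
    ics_adherence_mean: 81.5
    ics_laba_pct: 22.0
    ics_laba_adherence_mean: 84.2
    rescue_per_day_mean: 1.23
    rescue_per_day_sd: 1.47
    md_visits_mean: 1.56
    md_visits_sd: 2.94
    ed_visits_mean: 0.57
    ed_visits_sd: 1.69
    hosp_mean: 0.17
    hosp_sd: 0.75
  adolescent:
    male_pct: 52.1
    age_mean: 14.6
    age_sd: 1.6
    age_range: [12.0, 17.99]
    smoker_pct: 0.0
    fev1_pct_pred_mean: 80.5
    fev1_pct_pred_sd: 14.8
    ics_pct: 46.4
    ics_adherence_mean: 75.7
    ics_laba_pct: 25.1
    ics_laba_adherence_mean: 88.9
    rescue_per_day_mean: 0.57
    rescue_per_day_sd: 0.92
    md_visits_mean: 1.12
    md_visits_sd: 2.89
    ed_visits_mean: 0.51
    ed_visits_sd: 1.63
    hosp_mean: 0.06
    hosp_sd: 0.50
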