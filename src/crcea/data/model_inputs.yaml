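# Model inputs for the adjuvant-aspirin cost-effectiveness models in
# Stage I and Stage II colorectal cancer (US societal perspective).
#
# All resolved costs are November-2013 US dollars.  `raw` + `year` record
# the source amount (Medicare fee schedule, HCUP charge data, published
# cost studies); the medical-care CPI factors under `cpi_medical_2013`
# convert them.  Where a published 2013 figure and the recomputation
# disagree by more than a dollar, the published figure (`printed`) is
# authoritative and the drift is surfaced by the derivation audit, not
# silently recomputed away.
#
# Probabilities are annual.  `age_profile` entries interpolate linearly
# between the value at age 65 and the value at age 85.

common:
  start_age: 65
  horizon: 20
  cohort_size: 10000
  wtp: 100000
  discount: {cost_rate: 0.05, outcome_rate: 0.03}
  cpi_medical_2013: {2000: 1.64, 2005: 1.33, 2006: 1.28, 2007: 1.22, 2011: 1.07, 2013: 1.0}

  cost_items:
    aspirin_annual:
      {raw: 18, year: 2000, unit: per_year, printed: 30,
       note: daily 325 mg standard tablet applied in treatment years 1-5}
    capecitabine_month:
      {raw: 7263, year: 2006, unit: per_month, months: 1, printed: 9261,
       note: 1250 mg/m2 twice daily in 21-day cycles -- 8 cycles over 6 months}
    physician_visit: {raw: 143, year: 2013, unit: per_admin}
    blood_test: {raw: 11, year: 2013, unit: per_admin}
    cea_test: {raw: 26, year: 2013, unit: per_admin}
    ct_scan: {raw: 410, year: 2013, unit: per_admin}
    colonoscopy:
      {raw: 745, year: 2011, unit: per_admin, printed: 785,
       note: years 1 and 4 then every 5 years; recurrence surveillance only}
    metastatic_annual:
      {raw: 9798, year: 2008, unit: per_month, months: 12, printed: 138453,
       note: metastatic CRC care -- 9798/month = 117576/year in 2008 dollars}
    indirect_remission_annual:
      {raw: 255, year: 2013, unit: per_year,
       note: 0.88 h/month office-visit time x 12 x 24.15/h median wage}
    indirect_recurrence_annual:
      {raw: 10437, year: 2013, unit: per_year,
       note: terminal-phase time -- 432.17 h/year x 24.15/h median wage}
    capecitabine_ae_nonfatal_year:
      {raw: 674, year: 2006, unit: per_month, months: 6, printed: 5157,
       note: grade 3/4 hand-foot syndrome / diarrhea care over the 6-month regimen}
    capecitabine_ae_fatal_episode:
      {raw: 50248, year: 2011, unit: per_episode, printed: 53820,
       note: weighted pneumonia / septicemia / organ-failure terminal admission}

  surveillance_schedules:
    # physician visits quarterly in years 1-2 then annual; blood and CEA
    # quarterly in year 1 then annual; CT annual; colonoscopy years 1 and
    # 4 then 5-yearly.
    physician_visits_per_year: [4, 4, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    blood_tests_per_year:      [4, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    cea_tests_per_year:        [4, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    ct_scans_per_year:         [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    colonoscopy_years: [1, 4, 9, 14, 19]

  indirect_cost_years: 3   # patient-time costs until full retirement age

  # Aspirin bleeding events (annual probabilities by age, linear between
  # the age-65 and age-85 values; unit charges in 2005 dollars).  The
  # per-event probabilities are used as weights for the episode-cost
  # averages; the *total* AE transition probabilities of the aspirin arm
  # are the model inputs below.
  aspirin_ae_events:
    nonfatal:
      gi_bleed:     {p65: 0.0023, p85: 0.0058, cost: 21700, year: 2005}
      intracranial: {p65: 0.0013, p85: 0.0052, cost: 32400, year: 2005}
    fatal:
      gi_bleed:     {p65: 0.000072, p85: 0.00312, cost: 21700, year: 2005}
      intracranial: {p65: 0.00069, p85: 0.00276, cost: 32400, year: 2005}

  strategies:
    aspirin:
      rr_progression: 0.53
      rr_ci95: [0.33, 0.86]
      benefit_years: 5
      treatment_years: 5
      pill_utility: 0.999           # daily-pill disutility of 0.001
      pill_utility_range: [0.7992, 1.0]
      pill_utility_psa: {distribution: beta, mean: 0.999, sd: 0.00383}
      drug_cost_annual: 30
      drug_cost_range: [24, 36]
      p_fatal_ae: {age_profile: {p65: 0.0008, p85: 0.0030}, sa_range: [0.0, 0.03]}
      p_nonfatal_ae: {age_profile: {p65: 0.0036, p85: 0.0111}, sa_range: [0.0, 0.11]}
    capecitabine:
      rr_progression: 0.78
      rr_ci95: [0.67, 0.91]
      benefit_years: 5
      treatment_years: 1            # 6-month regimen collapsed into cycle 1
      drug_cost_first_year: 55569
      drug_cost_range: [44455, 66683]
      drug_cost_psa: {distribution: gamma, mean: 55569, sd: 1329}
      p_fatal_ae: {first_year: 0.003, sa_range: [0.0, 0.03]}
      p_fatal_ae_psa: {distribution: beta, alpha: 3, beta: 990}
      p_nonfatal_ae: {first_year: 0.0291, sa_range: [0.0233, 0.0349]}
      ae_nonfatal_cost_year: 5157
      ae_nonfatal_cost_range: [4125, 6188]
      ae_fatal_cost_episode: 53820
      ae_fatal_cost_range: [43056, 64583]
      extra_visits_first_year: 6    # 3-weekly visits during the 6-month regimen
    no_treatment: {}

  metastatic_sa_range: [69226, 276906]    # +/-50% (cost exceeds 100,000)
  metastatic_psa: {distribution: gamma, mean: 138453, sd: 630923}
  indirect_remission_range: [204, 306]
  indirect_recurrence_range: [8350, 12524]
  ae_cost_sa_fraction: [0.8, 1.2]         # +/-20% on the weighted AE episode costs

stage_I:
  strategies: [aspirin, no_treatment]
  utilities:
    remission_intervention: {value: 0.84, sa_range: [0.5068, 1.0], psa: {distribution: beta, mean: 0.84, sd: 0.17}}
    remission_discontinued: {value: 0.84, sa_range: [0.5068, 1.0], psa: {distribution: beta, mean: 0.84, sd: 0.17}}
    recurrence: {value: 0.84, sa_range: [0.6048, 1.0]}
  # Table-3-style PSA set for this stage
  psa_parameters: [metastatic_cost, p_fatal_ae_aspirin, p_nonfatal_ae_aspirin,
                   rr_aspirin, u_aspirin, u_remission_intervention, u_remission_discontinued]

stage_II:
  strategies: [aspirin, capecitabine, no_treatment]
  utilities:
    remission_intervention: {value: 0.86, sa_range: [0.5856, 1.0], psa: {distribution: beta, mean: 0.86, sd: 0.14}}
    remission_discontinued: {value: 0.86, sa_range: [0.5856, 1.0]}
    recurrence: {value: 0.84, sa_range: [0.6048, 1.0]}
  psa_parameters: [drug_cost_capecitabine, metastatic_cost, rr_aspirin, rr_capecitabine,
                   p_fatal_ae_aspirin, p_fatal_ae_capecitabine, p_nonfatal_ae_aspirin,
                   u_aspirin, u_remission_intervention]
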