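# Full default parameter file (2020 EUR; NOK/EUR 10.73).
# Every value here equals the package default; the file exists so analyses
# can be re-run from an explicit, versionable configuration.  Unknown keys
# are rejected at load time.

costs:
  ems_cost_per_transport: 559        # EUR per ambulance transport
  p_ambulance_to_primary: 0.29       # transports to emergency primary care
  p_ambulance_to_hospital_base: 0.90
  p_ambulance_to_hospital_conservative: 0.75
  consultation_cost: 166             # shared general consultation cost, EUR
  algorithm_lab_cost: 41             # hs-cTnT lab + additional diagnostics
  personnel_cost_wage: 99            # time on the 0/1-h algorithm, wage-costed
  personnel_cost_tariff: 137         # same, tariff-costed (conservative)
  outpatient_referral_cost: 52       # increased outpatient cardiac testing
  drg_total: 840664                  # DRG total of the low-risk hospital cohort
  n_hospital_cohort: 567
  nok_per_eur: 10.73
  payroll_multiplier: 1.3            # wage gross-up: payroll taxes etc.
  helfo_multiplier: 2.0              # HELFO reimbursement gross-up

time:
  los_primary_base_mean_h: 3.4
  los_primary_base_sd_h: 0.740
  los_primary_conservative_mean_h: 4.0
  los_primary_conservative_sd_h: 0.870
  los_hospital_mean_h: 22.3
  los_hospital_sd_h: 22.010
  hours_per_year: 8766               # 365.25 * 24

utility:
  waiting_utility_decrement: 0.232   # annualised utility lost while waiting
  qaly_loss_per_event: 2.222         # lifetime discounted QALYs per excess event
  remaining_qalys_no_event: 13.3     # anchor, age 56, no index event
  remaining_qalys_post_ami: 11.1     # anchor, age 56, after an AMI
  utility_non_cvd: 0.85
  utility_cvd: 0.74

events:
  rate_primary_30d: 0.003367003      # 5 / 1485 (AMI or death within 30 days)
  rate_hospital_30d: 0.002320186     # 2 / 862
  excess_rate_conservative: 0.001
  base_case_event_loss_zero: true

economics:
  discount_rate: 0.04
  threshold_low: 25600               # EUR per QALY, Norwegian band
  threshold_high: 76900
  reference_year: 2020

markov:
  start_age: 56
  max_age: 110
  gompertz_b: 2.0e-5
  gompertz_theta: 0.095
  hr_cvd_mortality: 1.6              # mortality hazard ratio while living with CVD
  annual_cvd_incidence: 0.01
  mortality_scale: 1.0               # calibration knob (fit to the QALY anchors)
  utility_scale: 1.0                 # calibration knob
  alive_tolerance: 1.0e-6
  first_cycle_exponent: 1            # discounting starts one period after index

# Overuse of hs-cTnT testing once available in primary care (10-15%);
# sensitivity use only — those patients are already in the primary cohort.
induced_testing_fraction: 0.15
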