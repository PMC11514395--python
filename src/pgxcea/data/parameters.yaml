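# Packaged base-case parameterization (costs in QAR, 3.64 QAR = 1 USD).
# The mortality table is a SYNTHETIC Gompertz stand-in (baseline 0.002/yr at
# age 48, doubling every 8 years) for the national life table, which is not
# bundled; supply a real schedule for applied work.
wtp: 546000.0   # USD 150,000 x 3.64, per QALY or life-year

tables:
  prevalence: prevalence.csv
  clinical: clinical.csv
  dispositions: dispositions.csv
  acquisition_costs: acquisition_costs.csv
  side_effect_costs: side_effect_costs.csv
  utilities: utilities.csv
  transitions: transitions.csv
  mortality: mortality_synthetic.csv

costs:
  short:
    event_relapse: 954.0
    event_suicide_death: 15.0
    event_suicide_attempt: 390.0
    event_nonsuicide_death: 1020.0
    event_survival: 1300.0
    consultation: 1000.0
    lab_screening: 560.0
    genotyping_panel: 540.0
    alternative_override: null
  long:
    acquisition:
      PGX: 648.0
      SOC: 595.0
    lab_screening: 560.0
    follow_up: 500.0
    event_relapse: 1908.0
    event_suicide_death: 29.0
    event_suicide_attempt: 779.0
    event_nonsuicide_death: 2040.0
    event_survival: 2600.0

markov:
  start_age: 48.0
  end_age: 81.0
  cycle_years: 0.25
  discount_rate: 0.03
  cohort_size: 15000
  variant: reconciled
  mortality_degree: 2

options:
  gene_weights:
    CYP2D6: 0.5
    CYP2C19: 0.5
  carrier_fraction: 1.0
  count_switch_success: false
  renormalize_dispositions: true
  use_dose_reduction: true
  charge_relapse_and_se_costs: true
  age_trends: true
  half_cycle: false
  horizon_years: null
  discount_on: true
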