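deck_version: 1
settings:
  discount_rate_annual: 0.03
  wtp_threshold: 50000.0
  horizon_years: 5.0
  cycle_plan:
  - 0.25
  - 0.25
  - 0.25
  - 0.25
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  reference_strategy: CT
  half_cycle_correction: false
  severity_cutoff_mild: 7.5
  severity_cutoff_moderate: 19.5
  truncate_ipss: false
  trajectory_rule: carry_forward
  days_per_year: 365.25
cohort:
  start_age: 63.0
  baseline_ipss_mean: 22.0
  baseline_ipss_sd: 4.8
  cohort_size: 1.0
tables:
  ae_rates: synthetic_ae_rates.csv
  costs: costs.csv
  ipss_trajectories: ipss_trajectories.csv
  life_table: synthetic_life_table.csv
  strategies: strategies.csv
  utilities: synthetic_utilities.csv
provenance:
  deck: 2021 US Medicare BPH cost-utility reference deck
  costs: published 2021 Medicare reimbursement inputs
  trajectories: published random-effects NMA IPSS table
  utilities: SYNTHETIC stand-in values (catalog not published at cell level); see
    synthetic_utilities.csv
  ae_rates: SYNTHETIC stand-in schedules; see synthetic_ae_rates.csv
  life_table: SYNTHETIC male life table; see synthetic_life_table.csv
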