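# Base-case run configuration: hydrophilic-coated vs uncoated PVC catheters
# for intermittent catheterization after spinal cord injury, Brazilian public
# healthcare perspective, lifetime horizon, monthly cycles, BRL.
#
# Values marked "assumption" are package choices (no published input exists);
# everything else is a published model input.
analysis: primary
seed: 0

cohort:
  entry_age: 36
  proportion_male: 0.80

# Monthly adverse-event probabilities, uncoated-PVC baseline.
event_rates:
  uti: 0.6248            # pooled across the four-trial evidence base
  bladder_stones: 0.0012
  kidney_stones: 0.0012
  urethral_injury: 0.0019
  urosepsis: 0.0032

# Relative risks, hydrophilic-coated vs PVC.
treatment_effect:
  uti: 0.84
  other_events: 0.90

# Antibiotic resistance cascade.
resistance:
  first_line: 0.34       # ciprofloxacin
  second_line: 0.034     # cefuroxime

# Monthly renal progression probabilities. Assumption: order-of-magnitude
# placeholders; no published values exist.
renal_progression:
  no_to_significant: 0.0004
  significant_to_failure: 0.0029

# Excess-hazard multipliers over background mortality.
mortality_multipliers:
  uti_first_line: 0.0
  uti_resistant: 145.27
  uti_weighted: 49.3918      # = 145.27 x 0.34; fixed input, see docs/methods.md
  urosepsis: 797.6
  significant_impairment: 18.0
  renal_failure: 54.0

flags:
  uti_mortality_mode: weighted   # resistance-weighted multiplier on UTI states
  rate_to_prob: false            # use the pooled monthly value as a probability
  half_cycle: false              # spreadsheet-style start-of-cycle accounting

# BRL, public-system prices.
costs:
  catheter_pvc_monthly: 74.27
  catheter_hydrophilic_monthly: 608.27
  lubricant_monthly: 132.75      # at 2 tubes/day
  tubes_per_day: 2.0
  uti_event: 554.16
  uti_antibiotics: 60.50
  urosepsis_event: 708.36
  urethral_injury_event: 605.33
  kidney_stones_event: 524.30
  bladder_stones_event: 721.95
  significant_impairment_monthly: 82.60
  renal_failure_monthly: 2589.02

utilities:
  baseline: 0.50                 # assumption: baseline utility of the cohort
  uti: 0.060
  uti_resistant: 0.104
  kidney_stones: 0.050
  bladder_stones: 0.050
  urethral_injury: 0.104
  urosepsis: 0.160
  significant_impairment: 0.155
  renal_failure: 0.250

economics:
  discount_rate_annual: 0.05
  threshold_per_qaly: 147000.0

# Synthetic Gompertz-Makeham life tables (stand-ins emulating Brazil 2014:
# life expectancy at birth ~71.4 y male, ~78.6 y female).
life_table:
  kind: synthetic
  age_start: 0
  age_end: 110
  male: {a: 0.0013, b: 0.00007, c: 1.092}
  female: {a: 0.0006, b: 0.000038, c: 1.094}
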