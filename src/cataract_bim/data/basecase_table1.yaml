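# Published UK base case: 3,000 phacoemulsification cataract operations/year,
# GBP (January 2015), one-year horizon, hospital perspective.
#
# Per-operation surgeon/theatre times are stored at the precision implied by
# the annual aggregates (601.25 h and 566.75 h over 3,000 operations give
# 12.025 and 11.335 min), i.e. back-derived from the resource-use totals
# rather than the 2-decimal rounded prints (12.03 / 11.34).
#
# revenue_per_operation is NOT a published input: the source prints only the
# resulting annual revenue for the operations gained.  744.70 is back-derived
# (27,412 / 36.81) and is plain configuration — change it to your tariff.
n_patients: 3000
nurse_rate: 43.12          # GBP/h
surgeon_rate: 147.26       # GBP/h
revenue_per_operation: 744.70

intervention:
  name: intracameral
  p_failure: 0.011
  wait_before_surgery_min: 8.70
  n_instillation_sessions: 0
  session_duration_min: 0.0
  surgeon_working_time_min: 12.025
  or_occupancy_min: 12.025
  extra_time_failure_min: 10.0
  between_op_loss_min: 10.0
  drug_unit_costs:
    mydrane: 6.00
  patients_per_vial: 1

reference:
  name: eye_drops
  p_failure: 0.053
  wait_before_surgery_min: 37.90
  n_instillation_sessions: 3
  session_duration_min: 3.0
  surgeon_working_time_min: 11.335
  or_occupancy_min: 11.335
  extra_time_failure_min: 10.0
  between_op_loss_min: 10.0
  drug_unit_costs:
    tropicamide: 0.54
    phenylephrine: 0.57
  patients_per_vial: 1

# Rescue mydriatics used on intra-operative failure.  Marginal probabilities
# (more than one treatment possible per failure; they need not sum to 1).
rescue:
  - {label: adrenaline, probability: 0.04, cost: 4.95}
  - {label: phenylephrine, probability: 0.93, cost: 0.57}
  - {label: tropicamide, probability: 0.14, cost: 0.54}
  - {label: mechanical_tools, probability: 0.04, cost: 56.80}
  - {label: cyclopentolate, probability: 0.32, cost: 0.56}
  - {label: others, probability: 0.00, cost: 0.00}

# One-way DSA bounds, stored verbatim from the published low/high columns
# (including the internally odd ones, e.g. failure extra time high < base).
# Entries with several moves vary those paths together: shared drug prices
# enter both the acquisition and the rescue costing, and the rescue
# probability columns form two alternative whole-mixture scenarios.
dsa_bounds:
  - {name: intervention.p_failure, low: 0.002, high: 0.032}
  - {name: reference.p_failure, low: 0.030, high: 0.087}
  - {name: reference.n_instillation_sessions, low: 2, high: 4}
  - {name: reference.session_duration_min, low: 1.5, high: 5.0}
  - {name: reference.patients_per_vial, low: 1, high: 5}
  - {name: intervention.wait_before_surgery_min, low: 8.19, high: 9.21}
  - {name: reference.wait_before_surgery_min, low: 36.73, high: 39.07}
  - {name: nurse_rate, low: 35.76, high: 59.95}
  - {name: intervention.surgeon_working_time_min, low: 11.51, high: 12.52}
  - {name: reference.surgeon_working_time_min, low: 10.64, high: 12.04}
  - {name: intervention.or_occupancy_min, low: 11.51, high: 12.52}
  - {name: reference.or_occupancy_min, low: 10.64, high: 12.04}
  - {name: intervention.extra_time_failure_min, low: 2.5, high: 7.5}
  - {name: reference.extra_time_failure_min, low: 2.5, high: 7.5}
  - {name: intervention.between_op_loss_min, low: 5.0, high: 20.0}
  - {name: reference.between_op_loss_min, low: 5.0, high: 20.0}
  - {name: intervention.drug_cost.mydrane, low: 3.00, high: 9.00}
  - {name: rescue.adrenaline.cost, low: 0.39, high: 8.31}
  - {name: rescue.mechanical_tools.cost, low: 28.40, high: 85.20}
  - {name: rescue.cyclopentolate.cost, low: 0.50, high: 12.96}
  - {name: surgeon_rate, low: 105.18, high: 189.33}
  - name: cost_phenylephrine
    moves:
      - {path: reference.drug_cost.phenylephrine, low: 0.57, high: 0.57}
      - {path: rescue.phenylephrine.cost, low: 0.57, high: 0.57}
  - name: cost_tropicamide
    moves:
      - {path: reference.drug_cost.tropicamide, low: 0.50, high: 1.60}
      - {path: rescue.tropicamide.cost, low: 0.50, high: 1.60}
  - name: rescue_mixture_distribution
    moves:
      - {path: rescue.adrenaline.probability, low: 0.39, high: 0.04}
      - {path: rescue.phenylephrine.probability, low: 0.57, high: 0.93}
      - {path: rescue.tropicamide.probability, low: 0.00, high: 0.14}
      - {path: rescue.mechanical_tools.probability, low: 0.05, high: 0.04}
      - {path: rescue.cyclopentolate.probability, low: 0.01, high: 0.32}
      - {path: rescue.others.probability, low: 0.00, high: 0.00}
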