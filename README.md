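# cataract-bim

A hospital-perspective budget impact model (BIM) comparing two strategies
for obtaining intra-operative mydriasis in phacoemulsification cataract
surgery over a one-year horizon:

* **Intervention** — a single intracameral injection of a combined
  mydriatic/anaesthetic (tropicamide + phenylephrine + lidocaine), given by
  the surgeon at the start of surgery;
* **Reference** — topical tropicamide 0.5% / phenylephrine 10% drops,
  instilled by nurses in repeated pre-operative sessions.

It is written for health economists and theatre managers who want to
re-run, audit, or adapt this kind of analysis: every input is an explicit,
validated YAML scenario, every published-table quantity is a tested
function, and a patient-level Monte-Carlo simulator verifies that the
deterministic results are the exact expectations of the underlying
stochastic process.

## The model

For a cohort of `n` operations/year, an arm with per-operation mydriasis
failure probability `p` and per-operation times (minutes) accrues annual
expectations

```
failures            F  = n·p
waiting-room hours      = n·wait / 60
nurse hours             = n·sessions·session_duration / 60
surgeon in-op hours     = n·working_time / 60
surgeon delay hours     = F·(extra_time + between_op_loss) / 60
total surgeon hours     = in-op + delay          (= theatre occupancy)
```

Costs (GBP/year) are `nurse hours × nurse rate + surgeon hours × surgeon
rate` (work-related) plus drug acquisition (`n · Σ unit costs /
patients_per_vial`) and expected rescue treatment (`F · Σᵢ pᵢ·cᵢ` over the
rescue mixture, whose marginal probabilities may sum to more than 1 and are
never renormalised). The budget impact is the incremental total
(intervention − reference); surgeon time freed converts into extra
operations via the intervention's expected per-operation surgeon time.
A one-way deterministic sensitivity analysis re-evaluates the incremental
total cost at each input's low/high bound (tornado analysis).

## Worked example

```python
>>> from cataract_bim import BudgetImpactModel
>>> results = BudgetImpactModel.base_case().fit()   # packaged UK base case
>>> print(results.summary())
Budget impact: intracameral mydriatic injection vs. topical drops
scenario fingerprint: e14c552b0b1ad6a5   cohort: 3000 operations/year (GBP)

Annual resource use
                            intervention  reference  difference
waiting_room_hours                435.00    1895.00     -1460.0
or_occupancy_hours                612.25     619.75        -7.5
expected_failures                  33.00     159.00      -126.0
surgeon_in_operation_hours        601.25     566.75        34.5
surgeon_delay_hours                11.00      53.00       -42.0
total_surgeon_hours               612.25     619.75        -7.5
nurse_hours                         0.00     450.00      -450.0

Annual costs
                        intervention  reference  difference
nurse_cost                      0.00   19404.00   -19404.00
surgeon_cost                90160.00   91264.00    -1104.00
work_related_cost           90160.00  110668.00   -20508.00
drug_acquisition_cost       18000.00    3330.00    14670.00
rescue_cost                   107.00     518.00     -410.00
treatment_related_cost      18107.00    3848.00    14260.00
total_cost                 108267.00  114516.00    -6249.00
cost_per_patient               36.09      38.17       -2.08

Hospital throughput benefit
                          value
surgeon_minutes_saved    450.00
operations_gained         36.75
additional_revenue     27367.00
expected_net_benefit   26041.00
```

Reading: at 3,000 operations/year the injectable's higher acquisition cost
(£18,000 vs £3,330) is more than offset by freed nurse time (450 h,
£19,404) and fewer intra-operative failures (33 vs 159), for a net annual
saving of ~£6,249 (−£2.08 per patient). The 7.5 surgeon-hours saved
correspond to ~36.75 additional operations per year. Revenue per operation
(here £744.70) is plain configuration, not an evidence-based input —
change it to your local tariff before reading the benefit rows.

Sensitivity and validation:

```python
>>> results.tornado_frame().head(3)[["parameter_path", "span", "sign_flip"]]
                      parameter_path     span  sign_flip
0     reference.session_duration_min  22638.0       True
1     intervention.drug_cost.mydrane  18000.0       True
2  reference.n_instillation_sessions  12936.0       True
>>> results.check_against_simulation(n_replicates=200, seed=1).passed
True
```

The same is available from the shell:

```bash
cataract-bim run      --config scenario.yaml --out out/
cataract-bim dsa      --config scenario.yaml --out out/ --plot
cataract-bim microsim --config scenario.yaml --out out/ --replicates 200 --seed 1
```

A scenario file only needs the fields that differ from the packaged base
case (`src/cataract_bim/data/basecase_table1.yaml`); everything else,
including the sensitivity bounds, falls back to the packaged defaults.

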