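# Methods

## Model structure

The package implements a deterministic two-arm cohort budget-impact model
with a one-year horizon and a hospital perspective (GBP, 2015 price year;
no discounting or inflation adjustment, by construction of the horizon).
The patient pathway is a simple decision tree: pre-operative preparation
(waiting, nurse drop instillation in the topical arm), the operation
itself, and — with per-operation probability `p_failure` — an
intra-operative mydriasis failure that triggers rescue treatment and adds
surgeon/theatre time. Annual aggregates are computed as exact expected
values; every aggregate is linear in the cohort size and in the expected
failure count `n·p`.

Deliberately excluded, mirroring the scope of the analysis the base-case
inputs come from: adverse events (identical short-term profiles across
arms), anaesthesia (identical protocol in both arms), post-operative
medication, hospital room/capital costs, and any patient or carer
perspective. Topical-anaesthetic instillations occur in both arms with no
cost inputs and are represented nowhere in the computation. Patient
waiting-room time is tracked as a resource but carries no cost.

## Accounting conventions

Two readings of the published aggregate tables are under-determined by the
input table alone; the package fixes them as follows:

* **Theatre occupancy includes both failure-delay components.** Annual
  operating-room occupancy is the no-failure occupancy plus the
  intra-operative extra time *and* the between-operation loss. This is the
  only accounting under which occupancy (612.25 / 619.75 h) equals total
  surgeon time in both arms, as the published resource-use table shows.
  Whether the between-operation loss truly occupies the theatre is an
  inference from those totals, not a stated fact.
* **Back-derived per-operation times.** The input table prints surgeon
  times rounded to 2 decimals (12.03 / 11.34 min) while the annual
  aggregates imply unrounded values (601.25 h / 3000 = 12.025 min;
  566.75 h / 3000 = 11.335 min). The packaged fixture stores the
  back-derived values so the resource-use aggregates reproduce exactly.
* **Occupancy and working time are separate parameters** even though their
  base values coincide; the sensitivity engine varies them independently
  (occupancy has no cost attached, so its tornado span is zero).

Expected failure counts are carried unrounded through all downstream
computation; rounding (pounds to the nearest pound, per-patient pounds to
pence, hours to 2 decimals) happens only in the reporting layer, because
chaining rounded intermediates compounds error. Published cost cells were
themselves computed from unrounded hourly rates (e.g. £19,406 for 450
nurse-hours implies a rate slightly above the printed £43.12), so golden
tests compare cost aggregates at ±0.1% while resource-use and acquisition
costs are exact.

## Rescue mixture

Rescue treatment on failure is costed as an expected cost per failure,
`Σᵢ pᵢ·cᵢ`, with component probabilities applied independently and never
renormalised: the published distribution is explicitly "more than 1
possible" (base mixture sums to 1.47). Independence across components is
the minimal assumption consistent with marginal frequencies being the only
published information; it is also exactly the assumption under which the
expected-cost formula holds, and the microsimulation draws components the
same way. The "others" component is stored explicitly with probability and
cost 0 so the mixture is closed under the printed labels.

## Throughput benefit

Surgeon minutes saved by the intervention divide by the intervention arm's
*expected* per-operation surgeon time — working time plus `p_failure ×`
(extra + between-operation) minutes, 12.245 min in the base case — to give
operations gained (≈36.75/year; the published 36.81 is ~0.16% away, an
artefact of input rounding, and the divisor definition is the closest
defensible reading of "time needed for a cataract surgery").
`revenue_per_operation` is **not** an evidence-based input: the source
prints only the resulting revenue, so the fixture carries a back-derived
£744.70 flagged as plain configuration. The net-benefit rule —
revenue − operations gained × intervention cost per patient — is likewise
a package choice; the published net-benefit figure is not derivable from
any printed combination of its own numbers and is deliberately not
reproduced.

## Sensitivity analysis

The one-way DSA re-evaluates the full model at each bounded input's low
and high value with all else at base, recording the incremental *total*
annual cost (the quantity a tornado's zero line refers to). Bounds are
stored verbatim from the published low/high columns, including internally
odd intervals (the failure extra-time interval 2.5–7.5 does not bracket
its base 10; evaluated as given, not repaired). Two bound structures go
beyond plain scalars: shared drug prices (tropicamide, phenylephrine)
move the acquisition and rescue uses of the price together, and the rescue
probability columns are treated as two alternative whole-mixture
scenarios, since component-wise they do not form intervals. Entries sort
by descending span with lexicographic tie-breaking so reruns are
byte-identical.

A finding worth flagging: with the base-case inputs, *three* bounds flip
the sign of the incremental cost — session duration at its low bound
(removes £9,702 of nurse cost), the injectable price at its high bound
(adds £9,000), and the session count at its low bound (removes £6,468,
against a base saving of ~£6,249, leaving +£219). The third flip is
arithmetically unavoidable given the inputs, although narrative summaries
of this analysis mention only the first two; the engine reports what the
numbers say.

## Microsimulation validation

The patient-level simulator realises the generative process whose
expectation the cohort engine computes: failure ~ Bernoulli(`p_failure`)
per operation; on failure each rescue component is used independently with
its marginal probability, and the failure adds the extra and
between-operation minutes. All other per-patient times are deterministic
given the failure flag — the published inputs carry no time variances —
so stochasticity enters only through the failure and rescue draws. A
replicate of the annual cohort is therefore fully summarised by binomial
counts, which is how `simulate_cohort` draws it (distributionally
identical to summing per-patient draws, and fast); `simulate_patients`
produces the per-patient record table for inspection. All randomness flows
through one seeded `numpy` generator; no global state.

`oracle_check` compares every annual aggregate against the replicate mean:
deterministic aggregates (waiting, nurse time, in-operation time,
acquisition and nurse costs) must match to floating-point precision;
stochastic aggregates must lie within 3 standard errors. With 200
replicates of 3,000 patients the default check passes for the fixed seeds
used in the tests; across arbitrary seeds a >3 SE excursion occurs in
roughly 3% of runs — the expected false-alarm rate of a 3 SE criterion
applied to a handful of effectively independent statistics (the aggregates
within an arm are driven by the same failure count, so one unlucky draw
fails several fields at once). Because the cohort model is *exactly* the
expectation of the simulator, passing this check validates the internal
consistency of the two implementations; it says nothing about how well
either describes a real theatre (no inter-patient correlation, no
scheduling/queueing dynamics, no time variances, no surgeon learning).

## Problem sizes and numerical choices

The test suite and acceptance script run the published cohort size (3,000
operations), a 24-entry DSA sweep, 200-replicate simulations, and 1,000
randomized-scenario property checks; all complete in a few seconds on one
CPU. Degenerate inputs are handled explicitly: a zero-patient cohort
yields all-zero summaries, a zero per-operation surgeon time makes the
throughput conversion a configuration error, degenerate bounds
(low = high = base) produce zero-span tornado entries, and a zero standard
error in the oracle check demands exact agreement. Scenario equality is
field-by-field; configuration fingerprints (SHA-256 of the canonical JSON
serialisation, truncated) guard against comparing a simulation summary
with a different scenario.
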