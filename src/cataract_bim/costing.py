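"""Annual costs per arm, incremental comparison, and throughput benefit.

Costs (GBP/year) follow the budget holder's ledger:

* work-related = nurse time x nurse rate  +  total surgeon time x surgeon
  rate (surgeon time includes failure-attributable delay);
* treatment-related = drug acquisition (one vial of each product per
  patient, divided by any vial sharing) + expected rescue cost, where the
  rescue mixture is costed as an expected cost per failure,
  sum over components of probability x unit cost, with no renormalisation
  (several rescue treatments may be used on the same patient).

The incremental result is intervention minus reference, field by field, at
full precision; a negative total is a saving from adopting the injectable.

Throughput converts surgeon time freed by the intervention into extra
operations: minutes saved divided by the intervention arm's expected
per-operation surgeon time (working time plus expected failure delay).
Revenue per operation is plain configuration — the model never asserts a
tariff — and the net-benefit rule nets off the marginal per-patient cost of
performing the gained operations under the intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .cohort import ResourceUseSummary, resource_use
from .parameters import ArmParameters, RescueMixture, ScenarioConfig

__all__ = [
    "CostSummary",
    "IncrementalResult",
    "ThroughputSummary",
    "expected_rescue_cost_per_failure",
    "drug_acquisition_cost",
    "arm_costs",
    "incremental",
    "throughput_benefit",
]


@dataclass(frozen=True)
class CostSummary:
    """Annual costs for one arm (GBP/year; per-patient in GBP)."""

    nurse_cost: float
    surgeon_cost: float
    work_related_cost: float
    drug_acquisition_cost: float
    rescue_cost: float
    treatment_related_cost: float
    total_cost: float
    cost_per_patient: float

    def __sub__(self, other: "CostSummary") -> "CostSummary":
        return CostSummary(
            **{
                f.name: getattr(self, f.name) - getattr(other, f.name)
                for f in fields(self)
            }
        )

    def __neg__(self) -> "CostSummary":
        return CostSummary(**{f.name: -getattr(self, f.name) for f in fields(self)})


@dataclass(frozen=True)
class IncrementalResult:
    """Field-wise intervention-minus-reference differences."""

    resource_use: ResourceUseSummary
    costs: CostSummary

    def __neg__(self) -> "IncrementalResult":
        return IncrementalResult(-self.resource_use, -self.costs)


@dataclass(frozen=True)
class ThroughputSummary:
    """Hospital benefit from surgeon time freed by the intervention."""

    surgeon_minutes_saved: float
    operations_gained: float
    additional_revenue: float
    expected_net_benefit: float


def expected_rescue_cost_per_failure(mix: RescueMixture) -> float:
    """Expected rescue-treatment cost per mydriasis failure."""
    return mix.expected_cost_per_failure()


def drug_acquisition_cost(arm: ArmParameters, n_patients: float) -> float:
    """Annual acquisition cost of the arm's mydriatic products."""
    return n_patients * arm.drug_cost_per_patient


def arm_costs(
    resource: ResourceUseSummary, arm: ArmParameters, config: ScenarioConfig
) -> CostSummary:
    """Annual cost summary for one arm given its resource use."""
    nurse = resource.nurse_hours * config.nurse_rate
    surgeon = resource.total_surgeon_hours * config.surgeon_rate
    drugs = drug_acquisition_cost(arm, config.n_patients)
    rescue = resource.expected_failures * expected_rescue_cost_per_failure(config.rescue)
    work = nurse + surgeon
    treatment = drugs + rescue
    total = work + treatment
    per_patient = total / config.n_patients if config.n_patients else 0.0
    return CostSummary(
        nurse_cost=nurse,
        surgeon_cost=surgeon,
        work_related_cost=work,
        drug_acquisition_cost=drugs,
        rescue_cost=rescue,
        treatment_related_cost=treatment,
        total_cost=total,
        cost_per_patient=per_patient,
    )


def incremental(
    intervention: tuple[ResourceUseSummary, CostSummary],
    reference: tuple[ResourceUseSummary, CostSummary],
) -> IncrementalResult:
    """Exact field-wise intervention-minus-reference differences."""
    iv_res, iv_cost = intervention
    rf_res, rf_cost = reference
    return IncrementalResult(iv_res - rf_res, iv_cost - rf_cost)


def throughput_benefit(
    incr: IncrementalResult,
    config: ScenarioConfig,
    intervention_costs: CostSummary | None = None,
) -> ThroughputSummary:
    """Operations gained from surgeon time saved, and the resulting benefit.

    Time saved is the (sign-flipped) total-surgeon-hours difference; the
    per-operation divisor is the intervention arm's expected surgeon time
    per operation, failure delay included.  A zero saving yields an all-zero
    summary.  Net benefit = revenue - operations_gained x intervention
    cost per patient (the marginal cost of actually performing them).
    """
    minutes_saved = -incr.resource_use.total_surgeon_hours * 60.0
    if minutes_saved == 0.0:
        return ThroughputSummary(0.0, 0.0, 0.0, 0.0)
    arm = config.intervention
    per_op_min = arm.surgeon_working_time_min + arm.p_failure * (
        arm.extra_time_failure_min + arm.between_op_loss_min
    )
    if per_op_min <= 0.0:
        raise ValueError(
            "intervention per-operation surgeon time is 0; cannot convert "
            "saved time into operations"
        )
    ops = minutes_saved / per_op_min
    revenue = ops * config.revenue_per_operation
    if intervention_costs is None:
        iv_res = resource_use(arm, config)
        intervention_costs = arm_costs(iv_res, arm, config)
    net = revenue - ops * intervention_costs.cost_per_patient
    return ThroughputSummary(
        surgeon_minutes_saved=minutes_saved,
        operations_gained=ops,
        additional_revenue=revenue,
        expected_net_benefit=net,
    )
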