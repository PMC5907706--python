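"""Patient-level Monte-Carlo twin of the cohort model.

The cohort engine computes expectations of a simple generative process:
each operation fails mydriasis with probability ``p_failure`` (Bernoulli);
on failure every rescue component is applied independently with its marginal
mixture probability (so several may be used, matching the expected-cost
formula sum of p_i * c_i with no renormalisation) and the failure adds the
extra intra-operative minutes plus the between-operation loss to surgeon and
theatre time.  All other per-patient times and the acquisition cost are
deterministic — the published inputs carry no time variances.

This module realises that process patient by patient and replicate by
replicate, so that the deterministic cohort results can be verified as the
exact expectation of the microsimulation (``oracle_check``): stochastic
aggregates must land within 3 standard errors of the cohort value, and
deterministic aggregates must match exactly.

All randomness flows through one :class:`numpy.random.Generator` derived
from an explicit seed; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import resource_use
from .costing import arm_costs
from .parameters import ArmParameters, ScenarioConfig, config_hash

__all__ = [
    "PatientRecord",
    "FieldStat",
    "MicrosimSummary",
    "OracleReport",
    "simulate_patient",
    "simulate_patients",
    "simulate_cohort",
    "oracle_check",
]

# Aggregates that are non-random given the inputs (no failure draw enters).
DETERMINISTIC_FIELDS = frozenset(
    {
        "waiting_room_hours",
        "surgeon_in_operation_hours",
        "nurse_hours",
        "nurse_cost",
        "drug_acquisition_cost",
    }
)

STOCHASTIC_FIELDS = (
    "failures",
    "surgeon_delay_hours",
    "total_surgeon_hours",
    "or_occupancy_hours",
    "surgeon_cost",
    "work_related_cost",
    "rescue_cost",
    "treatment_related_cost",
    "total_cost",
    "cost_per_patient",
)

ALL_FIELDS = tuple(sorted(DETERMINISTIC_FIELDS)) + STOCHASTIC_FIELDS


@dataclass(frozen=True)
class PatientRecord:
    """One simulated operation."""

    arm: str
    failed_mydriasis: bool
    wait_min: float
    nurse_min: float
    surgeon_min: float
    or_min: float
    rescue_components_used: tuple[str, ...]
    drug_cost: float
    rescue_cost: float


@dataclass(frozen=True)
class FieldStat:
    mean: float
    se: float


@dataclass
class MicrosimSummary:
    """Replicate means and standard errors of the annual aggregates."""

    n_patients: int
    n_replicates: int
    seed: int
    config_fingerprint: str
    arms: dict[str, dict[str, FieldStat]]
    # component uses / failures, pooled over replicates (estimates p_i)
    rescue_use_rate: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "n_patients": self.n_patients,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "config_fingerprint": self.config_fingerprint,
            "arms": {
                arm: {f: {"mean": s.mean, "se": s.se} for f, s in stats.items()}
                for arm, stats in self.arms.items()
            },
            "rescue_use_rate": self.rescue_use_rate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def simulate_patient(
    arm: ArmParameters, config: ScenarioConfig, rng: np.random.Generator
) -> PatientRecord:
    """Draw one patient's pathway through one operation."""
    failed = bool(rng.random() < arm.p_failure)
    used: list[str] = []
    rescue_cost = 0.0
    extra = 0.0
    if failed:
        for comp in config.rescue:
            if rng.random() < comp.probability:
                used.append(comp.label)
                rescue_cost += comp.unit_cost
        extra = arm.extra_time_failure_min + arm.between_op_loss_min
    return PatientRecord(
        arm=arm.name,
        failed_mydriasis=failed,
        wait_min=arm.wait_before_surgery_min,
        nurse_min=arm.n_instillation_sessions * arm.session_duration_min,
        surgeon_min=arm.surgeon_working_time_min + extra,
        or_min=arm.or_occupancy_min + extra,
        rescue_components_used=tuple(used),
        drug_cost=arm.drug_cost_per_patient,
        rescue_cost=rescue_cost,
    )


def simulate_patients(
    arm: ArmParameters, config: ScenarioConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate ``n`` patients; one row per :class:`PatientRecord` field."""
    records = [simulate_patient(arm, config, rng) for _ in range(n)]
    return pd.DataFrame(
        {
            "arm": [r.arm for r in records],
            "failed_mydriasis": [r.failed_mydriasis for r in records],
            "wait_min": [r.wait_min for r in records],
            "nurse_min": [r.nurse_min for r in records],
            "surgeon_min": [r.surgeon_min for r in records],
            "or_min": [r.or_min for r in records],
            "rescue_components_used": [
                "|".join(r.rescue_components_used) for r in records
            ],
            "drug_cost": [r.drug_cost for r in records],
            "rescue_cost": [r.rescue_cost for r in records],
        }
    )


def _replicate_aggregates(
    arm: ArmParameters, config: ScenarioConfig, n_replicates: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Annual aggregates per replicate, via sufficient statistics.

    A replicate is fully summarised by its failure count and per-component
    rescue-use counts (every other quantity is deterministic per patient),
    so counts are drawn as binomials instead of looping over patients; the
    distribution is identical to summing ``simulate_patient`` draws.
    """
    n = config.n_patients
    k = rng.binomial(n, arm.p_failure, size=n_replicates).astype(float)
    uses = {c.label: rng.binomial(k.astype(int), c.probability) for c in config.rescue}

    per_failure_min = arm.extra_time_failure_min + arm.between_op_loss_min
    delay_h = k * per_failure_min / 60.0
    in_op_h = np.full(n_replicates, n * arm.surgeon_working_time_min / 60.0)
    total_surgeon_h = in_op_h + delay_h
    or_h = n * arm.or_occupancy_min / 60.0 + delay_h
    nurse_h = np.full(
        n_replicates, n * arm.n_instillation_sessions * arm.session_duration_min / 60.0
    )
    nurse_cost = nurse_h * config.nurse_rate
    surgeon_cost = total_surgeon_h * config.surgeon_rate
    drug_cost = np.full(n_replicates, n * arm.drug_cost_per_patient)
    rescue_cost = sum(
        (uses[c.label] * c.unit_cost for c in config.rescue), np.zeros(n_replicates)
    )
    work = nurse_cost + surgeon_cost
    treatment = drug_cost + rescue_cost
    total = work + treatment
    agg = {
        "waiting_room_hours": np.full(
            n_replicates, n * arm.wait_before_surgery_min / 60.0
        ),
        "surgeon_in_operation_hours": in_op_h,
        "nurse_hours": nurse_h,
        "nurse_cost": nurse_cost,
        "drug_acquisition_cost": drug_cost,
        "failures": k,
        "surgeon_delay_hours": delay_h,
        "total_surgeon_hours": total_surgeon_h,
        "or_occupancy_hours": or_h,
        "surgeon_cost": surgeon_cost,
        "work_related_cost": work,
        "rescue_cost": rescue_cost,
        "treatment_related_cost": treatment,
        "total_cost": total,
        "cost_per_patient": total / n if n else np.zeros(n_replicates),
    }
    total_failures = k.sum()
    use_rate = {
        c.label: float(uses[c.label].sum() / total_failures) if total_failures else 0.0
        for c in config.rescue
    }
    return agg, use_rate


def simulate_cohort(
    config: ScenarioConfig, n_replicates: int, seed: int
) -> MicrosimSummary:
    """Replicate the annual cohort ``n_replicates`` times per arm.

    Identical ``(config, n_replicates, seed)`` give a bit-identical summary.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    arms: dict[str, dict[str, FieldStat]] = {}
    use_rates: dict[str, dict[str, float]] = {}
    for which in ("intervention", "reference"):
        arm = config.arm(which)
        agg, use_rate = _replicate_aggregates(arm, config, n_replicates, rng)
        stats = {}
        for name, values in agg.items():
            mean = float(values.mean())
            if n_replicates > 1:
                se = float(values.std(ddof=1) / math.sqrt(n_replicates))
            else:
                se = 0.0
            stats[name] = FieldStat(mean=mean, se=se)
        arms[which] = stats
        use_rates[which] = use_rate
    return MicrosimSummary(
        n_patients=config.n_patients,
        n_replicates=n_replicates,
        seed=seed,
        config_fingerprint=config_hash(config),
        arms=arms,
        rescue_use_rate=use_rates,
    )


@dataclass
class OracleReport:
    """Per-field comparison of cohort expectations against microsim means."""

    passed: bool
    table: pd.DataFrame  # arm, field, expected, mean, se, deterministic, ok

    def failures(self) -> pd.DataFrame:
        return self.table[~self.table["ok"]]


def cohort_expectations(config: ScenarioConfig, which: str) -> dict[str, float]:
    """The deterministic model's expected value of every microsim aggregate."""
    arm = config.arm(which)
    res = resource_use(arm, config)
    cost = arm_costs(res, arm, config)
    return {
        "waiting_room_hours": res.waiting_room_hours,
        "surgeon_in_operation_hours": res.surgeon_in_operation_hours,
        "nurse_hours": res.nurse_hours,
        "nurse_cost": cost.nurse_cost,
        "drug_acquisition_cost": cost.drug_acquisition_cost,
        "failures": res.expected_failures,
        "surgeon_delay_hours": res.surgeon_delay_hours,
        "total_surgeon_hours": res.total_surgeon_hours,
        "or_occupancy_hours": res.or_occupancy_hours,
        "surgeon_cost": cost.surgeon_cost,
        "work_related_cost": cost.work_related_cost,
        "rescue_cost": cost.rescue_cost,
        "treatment_related_cost": cost.treatment_related_cost,
        "total_cost": cost.total_cost,
        "cost_per_patient": cost.cost_per_patient,
    }


def oracle_check(config: ScenarioConfig, summary: MicrosimSummary) -> OracleReport:
    """Check that cohort expectations match the simulation, field by field.

    Stochastic fields pass when the cohort value lies within 3 standard
    errors of the replicate mean (exact agreement required if the SE is 0,
    e.g. degenerate probabilities); deterministic fields must agree to
    floating-point precision.  Refuses to compare a summary produced from a
    different configuration.
    """
    if summary.config_fingerprint != config_hash(config):
        raise ValueError(
            "configuration fingerprint mismatch: summary was produced from a "
            "different scenario; comparison refused"
        )
    rows = []
    for which in ("intervention", "reference"):
        expected = cohort_expectations(config, which)
        for name in ALL_FIELDS:
            stat = summary.arms[which][name]
            deterministic = name in DETERMINISTIC_FIELDS
            if deterministic or stat.se == 0.0:
                ok = math.isclose(
                    expected[name], stat.mean, rel_tol=1e-12, abs_tol=1e-9
                )
            else:
                ok = abs(expected[name] - stat.mean) <= 3.0 * stat.se
            rows.append(
                {
                    "arm": which,
                    "field": name,
                    "expected": expected[name],
                    "mean": stat.mean,
                    "se": stat.se,
                    "deterministic": deterministic,
                    "ok": ok,
                }
            )
    table = pd.DataFrame(rows)
    return OracleReport(passed=bool(table["ok"].all()), table=table)
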