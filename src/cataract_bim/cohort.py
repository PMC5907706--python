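"""Deterministic cohort (expectation) engine for annual resource use.

Annual aggregates are computed as exact expected values of the patient-level
process: with ``n`` operations a year and per-operation failure probability
``p``, the expected number of intra-operative mydriasis failures is ``n * p``
and every time aggregate is linear in it.  Nothing is rounded here — printed
tables round at the reporting layer only.

Accounting conventions:

* *Surgeon in-operation time* uses the no-failure per-operation working time
  only; failure-attributable time (extra intra-operative minutes plus the
  between-operation loss) is carried separately and the two sum to total
  surgeon time.
* *Operating-room occupancy* is the no-failure occupancy plus **both**
  failure delay components.  The between-operation loss is counted against
  the theatre as well as the surgeon; this is the only accounting under
  which occupancy equals total surgeon time when the per-operation occupancy
  and working-time inputs coincide, as they do in the base case.
* Patient waiting-room time carries no cost anywhere downstream; it is
  reported as a resource only.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .parameters import ArmParameters, ScenarioConfig

__all__ = [
    "ResourceUseSummary",
    "expected_failures",
    "waiting_room_hours",
    "nurse_hours",
    "failure_delay_hours",
    "resource_use",
]


@dataclass(frozen=True)
class ResourceUseSummary:
    """Annual resource use for one arm (hours/year unless noted)."""

    waiting_room_hours: float
    or_occupancy_hours: float
    expected_failures: float  # count/year, unrounded
    surgeon_in_operation_hours: float
    surgeon_delay_hours: float
    total_surgeon_hours: float
    nurse_hours: float

    def __sub__(self, other: "ResourceUseSummary") -> "ResourceUseSummary":
        return ResourceUseSummary(
            **{
                f.name: getattr(self, f.name) - getattr(other, f.name)
                for f in fields(self)
            }
        )

    def __neg__(self) -> "ResourceUseSummary":
        return ResourceUseSummary(
            **{f.name: -getattr(self, f.name) for f in fields(self)}
        )


def expected_failures(n_patients: float, p_failure: float) -> float:
    """Expected annual count of intra-operative mydriasis failures."""
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    if not 0.0 <= p_failure <= 1.0:
        raise ValueError("p_failure must lie in [0, 1]")
    return n_patients * p_failure

def waiting_room_hours(n_patients: float, wait_min: float) -> float:
    """Total annual patient time in the waiting room."""
    return n_patients * wait_min / 60.0

def nurse_hours(n_patients: float, sessions: float, session_min: float) -> float:
    """Total annual nurse time instilling pre-operative drops."""
    return n_patients * sessions * session_min / 60.0

def failure_delay_hours(failures: float, extra_min: float, between_op_min: float) -> float:
    """Annual surgeon time lost to failures (intra-op extra + between-op loss)."""
    return failures * (extra_min + between_op_min) / 60.0


def resource_use(arm: ArmParameters, config: ScenarioConfig) -> ResourceUseSummary:
    """Annual expected resource use of one arm under a scenario."""
    n = config.n_patients
    failures = expected_failures(n, arm.p_failure)
    delay = failure_delay_hours(
        failures, arm.extra_time_failure_min, arm.between_op_loss_min
    )
    in_operation = n * arm.surgeon_working_time_min / 60.0
    return ResourceUseSummary(
        waiting_room_hours=waiting_room_hours(n, arm.wait_before_surgery_min),
        or_occupancy_hours=n * arm.or_occupancy_min / 60.0 + delay,
        expected_failures=failures,
        surgeon_in_operation_hours=in_operation,
        surgeon_delay_hours=delay,
        total_surgeon_hours=in_operation + delay,
        nurse_hours=nurse_hours(
            n, arm.n_instillation_sessions, arm.session_duration_min
        ),
    )
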