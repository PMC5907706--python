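"""Model inputs for the mydriasis budget-impact model.

The model compares two strategies for obtaining intra-operative mydriasis in
phacoemulsification cataract surgery at a hospital performing a fixed annual
volume of operations:

* an *intervention* arm — a single intracameral injection of a combined
  mydriatic/anaesthetic given by the surgeon at the start of surgery, and
* a *reference* arm — topical tropicamide/phenylephrine drops instilled by
  nurses in repeated pre-operative sessions.

Every input lives in a :class:`ScenarioConfig`: per-arm clinical parameters
(:class:`ArmParameters`), the rescue-treatment mixture applied when mydriasis
fails intra-operatively (:class:`RescueMixture`), staff hourly rates, the
cohort size, and low/high bounds for the one-way deterministic sensitivity
analysis.  Scenario files are YAML; the packaged ``basecase_table1`` fixture
holds the published UK base case (GBP, January 2015, one-year horizon).

Scalar parameters are addressed by dotted paths (``reference.p_failure``,
``nurse_rate``, ``intervention.drug_cost.mydrane``,
``rescue.adrenaline.probability``) so the sensitivity engine can perturb any
input uniformly via :func:`set_parameter`.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "ScenarioError",
    "ScenarioValidationError",
    "RangeError",
    "ParameterPathError",
    "ArmParameters",
    "RescueComponent",
    "RescueMixture",
    "DsaBound",
    "ScenarioConfig",
    "load_scenario",
    "save_scenario",
    "base_case",
    "get_parameter",
    "set_parameter",
    "config_hash",
]

BASECASE_RESOURCE = "basecase_table1.yaml"


class ScenarioError(ValueError):
    """Base class for scenario configuration problems."""


class ScenarioValidationError(ScenarioError):
    """A field is missing, of the wrong type, or violates an invariant."""


class RangeError(ScenarioValidationError):
    """A numeric field lies outside its admissible range."""


class ParameterPathError(ScenarioError, KeyError):
    """A dotted parameter path does not resolve to a scalar input."""

    def __str__(self) -> str:  # KeyError quotes its args; keep a plain message
        return ValueError.__str__(self)


def _require_number(value: Any, name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ScenarioValidationError(f"{name}: expected a number, got {value!r}")
    return float(value)


def _require_nonneg(value: Any, name: str) -> float:
    x = _require_number(value, name)
    if x < 0:
        raise RangeError(f"{name}: must be >= 0, got {x}")
    return x


def _require_probability(value: Any, name: str) -> float:
    x = _require_number(value, name)
    if not 0.0 <= x <= 1.0:
        raise RangeError(f"{name}: probability must lie in [0, 1], got {x}")
    return x


@dataclass
class ArmParameters:
    """All per-arm inputs for one mydriasis strategy.

    Times are minutes; costs are GBP.  ``p_failure`` is the per-operation
    probability that mydriasis is insufficient during surgery and rescue
    treatment is needed.  ``surgeon_working_time_min`` and
    ``or_occupancy_min`` are the no-failure per-operation times; a failure
    adds ``extra_time_failure_min`` intra-operatively plus
    ``between_op_loss_min`` of surgeon time lost between operations.
    ``drug_unit_costs`` maps product label to unit cost, and
    ``patients_per_vial`` spreads the (eye-drop) vial cost over patients.
    """

    name: str
    p_failure: float
    wait_before_surgery_min: float
    n_instillation_sessions: float
    session_duration_min: float
    surgeon_working_time_min: float
    or_occupancy_min: float
    extra_time_failure_min: float
    between_op_loss_min: float
    drug_unit_costs: dict[str, float]
    patients_per_vial: float = 1.0

    _DURATIONS = (
        "wait_before_surgery_min",
        "session_duration_min",
        "surgeon_working_time_min",
        "or_occupancy_min",
        "extra_time_failure_min",
        "between_op_loss_min",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prefix = f"arm {self.name!r}"
        self.p_failure = _require_probability(self.p_failure, f"{prefix}.p_failure")
        for f in self._DURATIONS:
            setattr(self, f, _require_nonneg(getattr(self, f), f"{prefix}.{f}"))
        self.n_instillation_sessions = _require_nonneg(
            self.n_instillation_sessions, f"{prefix}.n_instillation_sessions"
        )
        self.patients_per_vial = _require_number(
            self.patients_per_vial, f"{prefix}.patients_per_vial"
        )
        if self.patients_per_vial < 1:
            raise RangeError(f"{prefix}.patients_per_vial: must be >= 1")
        if not self.drug_unit_costs:
            raise ScenarioValidationError(f"{prefix}.drug_unit_costs: must be non-empty")
        self.drug_unit_costs = {
            str(k): _require_nonneg(v, f"{prefix}.drug_unit_costs[{k}]")
            for k, v in self.drug_unit_costs.items()
        }

    @property
    def drug_cost_per_patient(self) -> float:
        """Acquisition cost per patient: sum of unit costs over vial sharing."""
        return sum(self.drug_unit_costs.values()) / self.patients_per_vial


@dataclass
class RescueComponent:
    """One rescue mydriatic option: marginal use probability and unit cost."""

    label: str
    probability: float
    unit_cost: float

    def __post_init__(self) -> None:
        self.probability = _require_probability(
            self.probability, f"rescue.{self.label}.probability"
        )
        self.unit_cost = _require_nonneg(self.unit_cost, f"rescue.{self.label}.cost")


@dataclass
class RescueMixture:
    """Rescue treatments applied on mydriasis failure.

    Each component is used independently with its marginal probability, so
    the probabilities may sum to more than 1 (several rescue treatments can
    be applied to the same patient); they are never renormalised.
    """

    components: list[RescueComponent]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ScenarioValidationError("rescue: duplicate component labels")

    def __iter__(self) -> Iterator[RescueComponent]:
        return iter(self.components)

    def expected_cost_per_failure(self) -> float:
        """Expected rescue cost per failed mydriasis: sum of p_i * c_i."""
        return sum(c.probability * c.unit_cost for c in self.components)

    def component(self, label: str) -> RescueComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise ParameterPathError(f"rescue: no component {label!r}")


@dataclass
class DsaBound:
    """One named sensitivity-analysis entry.

    ``moves`` lists (path, low, high) triples varied *together*: a plain
    scalar bound has one move whose path equals ``name``; grouped entries
    (a drug price used in several places, or the whole rescue-probability
    distribution switched as one scenario) carry several.
    """

    name: str
    moves: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.moves:
            raise ScenarioValidationError(f"dsa_bounds[{self.name}]: no moves")
        self.moves = [
            (str(p), _require_number(lo, f"dsa_bounds[{self.name}].low"),
             _require_number(hi, f"dsa_bounds[{self.name}].high"))
            for p, lo, hi in self.moves
        ]


@dataclass
class ScenarioConfig:
    """Complete input set for one budget-impact scenario."""

    n_patients: int
    nurse_rate: float
    surgeon_rate: float
    intervention: ArmParameters
    reference: ArmParameters
    rescue: RescueMixture
    revenue_per_operation: float = 0.0
    dsa_bounds: list[DsaBound] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = _require_nonneg(self.n_patients, "n_patients")
        if n != int(n):
            raise ScenarioValidationError("n_patients: must be an integer")
        self.n_patients = int(n)
        self.nurse_rate = _require_nonneg(self.nurse_rate, "nurse_rate")
        self.surgeon_rate = _require_nonneg(self.surgeon_rate, "surgeon_rate")
        self.revenue_per_operation = _require_nonneg(
            self.revenue_per_operation, "revenue_per_operation"
        )
        self.intervention.validate()
        self.reference.validate()
        for bound in self.dsa_bounds:
            for path, _lo, _hi in bound.moves:
                get_parameter(self, path)  # raises ParameterPathError if dangling

    @property
    def arms(self) -> tuple[ArmParameters, ArmParameters]:
        return (self.intervention, self.reference)

    def arm(self, which: str) -> ArmParameters:
        try:
            return {"intervention": self.intervention, "reference": self.reference}[which]
        except KeyError:
            raise ParameterPathError(f"unknown arm {which!r}") from None

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def arm_dict(a: ArmParameters) -> dict[str, Any]:
            return {
                "name": a.name,
                "p_failure": a.p_failure,
                "wait_before_surgery_min": a.wait_before_surgery_min,
                "n_instillation_sessions": a.n_instillation_sessions,
                "session_duration_min": a.session_duration_min,
                "surgeon_working_time_min": a.surgeon_working_time_min,
                "or_occupancy_min": a.or_occupancy_min,
                "extra_time_failure_min": a.extra_time_failure_min,
                "between_op_loss_min": a.between_op_loss_min,
                "drug_unit_costs": dict(a.drug_unit_costs),
                "patients_per_vial": a.patients_per_vial,
            }

        return {
            "n_patients": self.n_patients,
            "nurse_rate": self.nurse_rate,
            "surgeon_rate": self.surgeon_rate,
            "revenue_per_operation": self.revenue_per_operation,
            "intervention": arm_dict(self.intervention),
            "reference": arm_dict(self.reference),
            "rescue": [
                {"label": c.label, "probability": c.probability, "cost": c.unit_cost}
                for c in self.rescue
            ],
            "dsa_bounds": [
                {
                    "name": b.name,
                    "moves": [
                        {"path": p, "low": lo, "high": hi} for p, lo, hi in b.moves
                    ],
                }
                for b in self.dsa_bounds
            ],
        }

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ScenarioConfig":
        def build_arm(key: str) -> ArmParameters:
            d = raw.get(key)
            if not isinstance(d, Mapping):
                raise ScenarioValidationError(f"{key}: missing or not a mapping")
            known = {f.name for f in fields(ArmParameters)}
            unknown = set(d) - known
            if unknown:
                raise ScenarioValidationError(
                    f"{key}: unknown field(s) {sorted(unknown)}"
                )
            try:
                return ArmParameters(**d)
            except TypeError as exc:
                raise ScenarioValidationError(f"{key}: {exc}") from None

        if not isinstance(raw, Mapping):
            raise ScenarioValidationError("scenario: top level must be a mapping")
        known_top = {
            "n_patients", "nurse_rate", "surgeon_rate", "revenue_per_operation",
            "intervention", "reference", "rescue", "dsa_bounds",
        }
        unknown = set(raw) - known_top
        if unknown:
            raise ScenarioValidationError(f"scenario: unknown field(s) {sorted(unknown)}")
        for key in ("n_patients", "nurse_rate", "surgeon_rate", "rescue"):
            if key not in raw:
                raise ScenarioValidationError(f"scenario: missing required field {key!r}")

        rescue_raw = raw["rescue"]
        if not isinstance(rescue_raw, list) or not rescue_raw:
            raise ScenarioValidationError("rescue: must be a non-empty list")
        rescue = RescueMixture(
            [
                RescueComponent(str(c["label"]), c["probability"], c["cost"])
                for c in rescue_raw
            ]
        )
        bounds = [
            DsaBound(
                name=str(b["name"]),
                moves=[
                    (m["path"], m["low"], m["high"])
                    for m in (b["moves"] if "moves" in b
                              else [{"path": b["name"], "low": b["low"], "high": b["high"]}])
                ],
            )
            for b in raw.get("dsa_bounds", [])
        ]
        return cls(
            n_patients=raw["n_patients"],
            nurse_rate=raw["nurse_rate"],
            surgeon_rate=raw["surgeon_rate"],
            intervention=build_arm("intervention"),
            reference=build_arm("reference"),
            rescue=rescue,
            revenue_per_operation=raw.get("revenue_per_operation", 0.0),
            dsa_bounds=bounds,
        )


# -- file I/O ----------------------------------------------------------


def _basecase_dict() -> dict[str, Any]:
    text = resources.files("cataract_bim.data").joinpath(BASECASE_RESOURCE).read_text()
    return yaml.safe_load(text)


def base_case() -> ScenarioConfig:
    """The packaged published base case (3,000 operations/year, GBP 2015)."""
    return ScenarioConfig.from_dict(_basecase_dict())


def load_scenario(path: str) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file.

    Top-level fields omitted from the file (including ``dsa_bounds``) fall
    back to the packaged base-case defaults, so a minimal file need only
    state what differs from the published scenario.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ScenarioValidationError(f"{path}: unparseable scenario file: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ScenarioValidationError(f"{path}: top level must be a mapping")
    merged = _basecase_dict()
    merged.update(raw)
    return ScenarioConfig.from_dict(merged)


def save_scenario(config: ScenarioConfig, path: str) -> None:
    """Write a scenario to YAML; ``load_scenario`` round-trips it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# -- dotted parameter paths -------------------------------------------

_TOP_SCALARS = ("n_patients", "nurse_rate", "surgeon_rate", "revenue_per_operation")
_ARM_SCALARS = (
    "p_failure",
    "wait_before_surgery_min",
    "n_instillation_sessions",
    "session_duration_min",
    "surgeon_working_time_min",
    "or_occupancy_min",
    "extra_time_failure_min",
    "between_op_loss_min",
    "patients_per_vial",
)


def _resolve(config: ScenarioConfig, path: str):
    """Return (container, attribute-or-key) for a dotted path."""
    parts = path.split(".")
    if len(parts) == 1:
        if parts[0] in _TOP_SCALARS:
            return config, parts[0]
        raise ParameterPathError(f"unknown parameter path {path!r}")
    head, rest = parts[0], parts[1:]
    if head in ("intervention", "reference"):
        arm = config.arm(head)
        if len(rest) == 1 and rest[0] in _ARM_SCALARS:
            return arm, rest[0]
        if len(rest) == 2 and rest[0] == "drug_cost":
            if rest[1] not in arm.drug_unit_costs:
                raise ParameterPathError(f"{head}: no drug {rest[1]!r}")
            return arm.drug_unit_costs, rest[1]
    elif head == "rescue" and len(rest) == 2:
        comp = config.rescue.component(rest[0])
        if rest[1] == "probability":
            return comp, "probability"
        if rest[1] == "cost":
            return comp, "unit_cost"
    raise ParameterPathError(f"unknown parameter path {path!r}")


def get_parameter(config: ScenarioConfig, path: str) -> float:
    """Read the scalar at a dotted parameter path."""
    container, key = _resolve(config, path)
    if isinstance(container, dict):
        return container[key]
    return getattr(container, key)


def set_parameter(config: ScenarioConfig, path: str, value: float) -> ScenarioConfig:
    """Return a new configuration differing from ``config`` only at ``path``.

    The original is untouched; the result is re-validated, so out-of-range
    values raise :class:`RangeError`.
    """
    new = copy.deepcopy(config)
    container, key = _resolve(new, path)
    if isinstance(container, dict):
        container[key] = _require_number(value, path)
    else:
        setattr(container, key, value)
    new.validate()
    return new


def config_hash(config: ScenarioConfig) -> str:
    """Stable fingerprint of a configuration's full input set."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
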