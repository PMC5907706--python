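import math

import numpy as np
import pytest

from cataract_bim import (
    ArmParameters,
    BudgetImpactModel,
    RescueComponent,
    RescueMixture,
    ScenarioConfig,
    arm_costs,
    base_case,
    incremental,
    resource_use,
)


@pytest.fixture
def base_config():
    return base_case()


@pytest.fixture
def base_results():
    return BudgetImpactModel.base_case().fit()


def random_arm(rng: np.random.Generator, name: str) -> ArmParameters:
    return ArmParameters(
        name=name,
        p_failure=float(rng.uniform(0, 1)),
        wait_before_surgery_min=float(rng.uniform(0, 60)),
        n_instillation_sessions=int(rng.integers(0, 6)),
        session_duration_min=float(rng.uniform(0, 10)),
        surgeon_working_time_min=float(rng.uniform(1, 30)),
        or_occupancy_min=float(rng.uniform(1, 30)),
        extra_time_failure_min=float(rng.uniform(0, 20)),
        between_op_loss_min=float(rng.uniform(0, 30)),
        drug_unit_costs={"drug_a": float(rng.uniform(0, 50))},
        patients_per_vial=float(rng.integers(1, 6)),
    )


def random_config(rng: np.random.Generator) -> ScenarioConfig:
    mixture = RescueMixture(
        [
            RescueComponent(f"comp{i}", float(rng.uniform(0, 1)), float(rng.uniform(0, 60)))
            for i in range(int(rng.integers(1, 5)))
        ]
    )
    return ScenarioConfig(
        n_patients=int(rng.integers(1, 5001)),
        nurse_rate=float(rng.uniform(0, 100)),
        surgeon_rate=float(rng.uniform(0, 300)),
        intervention=random_arm(rng, "iv"),
        reference=random_arm(rng, "rf"),
        rescue=mixture,
        revenue_per_operation=float(rng.uniform(0, 1000)),
    )


def evaluate(config: ScenarioConfig):
    """Resource use, costs and incremental for both arms of a scenario."""
    res = {w: resource_use(config.arm(w), config) for w in ("intervention", "reference")}
    cost = {w: arm_costs(res[w], config.arm(w), config) for w in ("intervention", "reference")}
    incr = incremental(
        (res["intervention"], cost["intervention"]),
        (res["reference"], cost["reference"]),
    )
    return res, cost, incr


def assert_cost_identities(config: ScenarioConfig) -> None:
    """Ledger identities hold to machine precision for both arms."""
    _, cost, _ = evaluate(config)
    for c in cost.values():
        assert math.isclose(c.work_related_cost, c.nurse_cost + c.surgeon_cost, rel_tol=1e-12)
        assert math.isclose(
            c.treatment_related_cost, c.drug_acquisition_cost + c.rescue_cost, rel_tol=1e-12
        )
        assert math.isclose(
            c.total_cost, c.work_related_cost + c.treatment_related_cost, rel_tol=1e-12
        )
        assert math.isclose(
            c.cost_per_patient * config.n_patients, c.total_cost, rel_tol=1e-9, abs_tol=1e-9
        )
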