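"""Cost aggregation, incremental comparison, and throughput benefit."""

import dataclasses

import pytest

from cataract_bim import (
    RescueComponent,
    RescueMixture,
    arm_costs,
    incremental,
    resource_use,
    set_parameter,
    throughput_benefit,
)
from cataract_bim.costing import drug_acquisition_cost, expected_rescue_cost_per_failure
from conftest import evaluate

# Sum of probability x unit cost over the published rescue mixture,
# computed by hand: .04*4.95 + .93*0.57 + .14*0.54 + .04*56.80 + .32*0.56
RESCUE_COST_PER_FAILURE = 3.2549


def test_expected_rescue_cost_per_failure(base_config):
    assert expected_rescue_cost_per_failure(base_config.rescue) == pytest.approx(
        RESCUE_COST_PER_FAILURE, abs=1e-12
    )
    # annual rescue costs round to the published pounds
    assert round(33 * RESCUE_COST_PER_FAILURE) == 107
    assert round(159 * RESCUE_COST_PER_FAILURE) == 518


def test_rescue_mixture_edge_cases():
    zero = RescueMixture([RescueComponent("a", 0.0, 5.0), RescueComponent("b", 0.0, 1.0)])
    assert expected_rescue_cost_per_failure(zero) == 0.0
    single = RescueMixture([RescueComponent("a", 1.0, 7.25)])
    assert expected_rescue_cost_per_failure(single) == 7.25


def test_drug_acquisition_costs(base_config):
    assert drug_acquisition_cost(base_config.intervention, 3000) == pytest.approx(18000.0)
    assert drug_acquisition_cost(base_config.reference, 3000) == pytest.approx(3330.0)
    shared = set_parameter(base_config, "reference.patients_per_vial", 5)
    assert drug_acquisition_cost(shared.reference, 3000) == pytest.approx(666.0)


def test_base_case_costs_match_published_totals(base_config):
    _, cost, _ = evaluate(base_config)
    iv, rf = cost["intervention"], cost["reference"]
    # published pounds come from rounded hourly-rate prints: +/-0.1%
    assert iv.total_cost == pytest.approx(108264, rel=1e-3)
    assert rf.total_cost == pytest.approx(114515, rel=1e-3)
    assert rf.nurse_cost == pytest.approx(19406, rel=1e-3)
    assert iv.nurse_cost == 0.0
    assert iv.surgeon_cost == pytest.approx(90157, rel=1e-3)
    assert rf.surgeon_cost == pytest.approx(91261, rel=1e-3)
    assert iv.drug_acquisition_cost == pytest.approx(18000.0)
    assert rf.drug_acquisition_cost == pytest.approx(3330.0)
    assert round(iv.rescue_cost) == 107
    assert round(rf.rescue_cost) == 518
    assert iv.cost_per_patient == pytest.approx(36.09, rel=1e-3)
    assert rf.cost_per_patient == pytest.approx(38.17, rel=1e-3)


def test_base_case_incremental_saving(base_config):
    _, _, incr = evaluate(base_config)
    assert incr.costs.total_cost == pytest.approx(-6251, rel=1e-3)
    assert incr.costs.work_related_cost == pytest.approx(-20511, rel=1e-3)
    assert incr.costs.rescue_cost == pytest.approx(-410, rel=1e-2)


def test_all_zero_rates_and_prices_give_zero_costs(base_config):
    cfg = base_config
    for path in ("nurse_rate", "surgeon_rate", "intervention.drug_cost.mydrane"):
        cfg = set_parameter(cfg, path, 0.0)
    for comp in cfg.rescue:
        cfg = set_parameter(cfg, f"rescue.{comp.label}.cost", 0.0)
    summary = arm_costs(resource_use(cfg.intervention, cfg), cfg.intervention, cfg)
    assert all(getattr(summary, f.name) == 0.0 for f in dataclasses.fields(summary))


def test_incremental_is_antisymmetric(base_config):
    res, cost, _ = evaluate(base_config)
    iv = (res["intervention"], cost["intervention"])
    rf = (res["reference"], cost["reference"])
    forward, backward = incremental(iv, rf), incremental(rf, iv)
    for f in dataclasses.fields(forward.costs):
        assert getattr(forward.costs, f.name) == -getattr(backward.costs, f.name)
    for f in dataclasses.fields(forward.resource_use):
        assert getattr(forward.resource_use, f.name) == -getattr(
            backward.resource_use, f.name
        )
    self_incr = incremental(iv, iv)
    assert all(
        getattr(self_incr.costs, f.name) == 0.0
        for f in dataclasses.fields(self_incr.costs)
    )


def test_equal_failure_probabilities_zero_the_rescue_difference(base_config):
    cfg = set_parameter(base_config, "intervention.p_failure", 0.053)
    _, _, incr = evaluate(cfg)
    assert incr.costs.rescue_cost == 0.0


def test_throughput_operations_gained(base_config):
    _, cost, incr = evaluate(base_config)
    benefit = throughput_benefit(incr, base_config, cost["intervention"])
    assert benefit.surgeon_minutes_saved == pytest.approx(450.0)
    # 450 saved minutes / (12.025 + 0.011 * 20) expected minutes per operation
    assert benefit.operations_gained == pytest.approx(450.0 / 12.245, rel=1e-12)
    assert benefit.additional_revenue == pytest.approx(
        benefit.operations_gained * 744.70, rel=1e-12
    )
    assert benefit.expected_net_benefit == pytest.approx(
        benefit.additional_revenue
        - benefit.operations_gained * cost["intervention"].cost_per_patient,
        rel=1e-12,
    )


def test_throughput_is_linear_in_revenue_per_operation(base_config):
    _, cost, incr = evaluate(base_config)
    doubled = set_parameter(
        base_config, "revenue_per_operation", 2 * base_config.revenue_per_operation
    )
    b1 = throughput_benefit(incr, base_config, cost["intervention"])
    b2 = throughput_benefit(incr, doubled, cost["intervention"])
    assert b2.additional_revenue == pytest.approx(2 * b1.additional_revenue)
    assert b2.operations_gained == b1.operations_gained


def test_zero_time_saved_gives_all_zero_benefit(base_config):
    res, cost, _ = evaluate(base_config)
    iv = (res["intervention"], cost["intervention"])
    benefit = throughput_benefit(incremental(iv, iv), base_config, cost["intervention"])
    assert benefit.surgeon_minutes_saved == 0.0
    assert benefit.operations_gained == 0.0
    assert benefit.additional_revenue == 0.0
    assert benefit.expected_net_benefit == 0.0


def test_zero_per_operation_time_is_a_configuration_error(base_config):
    cfg = set_parameter(base_config, "intervention.surgeon_working_time_min", 0.0)
    cfg = set_parameter(cfg, "intervention.p_failure", 0.0)
    _, cost, incr = evaluate(cfg)
    with pytest.raises(ValueError, match="per-operation"):
        throughput_benefit(incr, cfg, cost["intervention"])
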