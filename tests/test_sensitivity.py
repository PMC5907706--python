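"""One-way deterministic sensitivity analysis and tornado ordering."""

import copy

import pytest

from cataract_bim import DsaBound, one_way_dsa, set_parameter, tornado_table
from cataract_bim.sensitivity import TornadoEntry, incremental_total_cost


def entries_by_name(entries):
    return {e.parameter_path: e for e in entries}


def test_sweep_does_not_mutate_the_base_configuration(base_config):
    before = copy.deepcopy(base_config)
    base_incr = incremental_total_cost(base_config)
    one_way_dsa(base_config)
    assert base_config == before
    assert incremental_total_cost(base_config) == base_incr


def test_single_scalar_entries_agree_with_direct_reruns(base_config):
    """Each entry equals independently re-running the full model at the bound."""
    entries = entries_by_name(one_way_dsa(base_config))
    for bound in base_config.dsa_bounds:
        if len(bound.moves) != 1:
            continue
        path, low, high = bound.moves[0]
        expected_low = incremental_total_cost(set_parameter(base_config, path, low))
        expected_high = incremental_total_cost(set_parameter(base_config, path, high))
        entry = entries[bound.name]
        assert entry.incremental_at_low == pytest.approx(expected_low, rel=1e-12)
        assert entry.incremental_at_high == pytest.approx(expected_high, rel=1e-12)


def test_grouped_entries_move_all_paths_together(base_config):
    entries = entries_by_name(one_way_dsa(base_config))
    cfg = base_config
    for path, low, _ in entries_by_name_moves(base_config, "rescue_mixture_distribution"):
        cfg = set_parameter(cfg, path, low)
    assert entries["rescue_mixture_distribution"].incremental_at_low == pytest.approx(
        incremental_total_cost(cfg), rel=1e-12
    )


def entries_by_name_moves(config, name):
    (bound,) = [b for b in config.dsa_bounds if b.name == name]
    return bound.moves


def test_intervention_price_at_high_bound_flips_the_saving(base_config):
    """+GBP 3 per injection over 3,000 operations outweighs the base saving."""
    base_incr = incremental_total_cost(base_config)
    entry = entries_by_name(one_way_dsa(base_config))["intervention.drug_cost.mydrane"]
    assert entry.incremental_at_high == pytest.approx(base_incr + 9000, rel=1e-9)
    assert entry.incremental_at_high > 0 > base_incr
    assert entry.sign_flip


def test_costless_resources_have_zero_span(base_config):
    """Waiting-room time and theatre occupancy carry no cost, so varying
    them cannot move the incremental cost."""
    entries = entries_by_name(one_way_dsa(base_config))
    base_incr = incremental_total_cost(base_config)
    for name in (
        "intervention.wait_before_surgery_min",
        "reference.wait_before_surgery_min",
        "intervention.or_occupancy_min",
        "reference.or_occupancy_min",
    ):
        assert entries[name].span == pytest.approx(0.0, abs=1e-9)
        assert entries[name].incremental_at_low == pytest.approx(base_incr, rel=1e-12)


def test_degenerate_bounds_reproduce_the_base_incremental(base_config):
    # the phenylephrine price interval is degenerate (low = high = base)
    entry = entries_by_name(one_way_dsa(base_config))["cost_phenylephrine"]
    base_incr = incremental_total_cost(base_config)
    assert entry.incremental_at_low == pytest.approx(base_incr, rel=1e-12)
    assert entry.incremental_at_high == pytest.approx(base_incr, rel=1e-12)
    assert entry.span == pytest.approx(0.0, abs=1e-9)
    assert not entry.sign_flip


def test_sign_flips_identify_parameters_that_overturn_the_conclusion(base_config):
    """Three bounds can individually overturn the base-case saving.

    The base saving is ~GBP 6,249/year.  Halving the instillation-session
    duration removes 225 nurse-hours (~GBP 9,702) from the reference arm;
    the injectable at GBP 9 adds GBP 9,000 to the intervention arm; and
    dropping from three to two instillation sessions removes 150
    nurse-hours (~GBP 6,468) — each exceeds the saving, so each flips the
    incremental's sign.
    """
    flips = {e.parameter_path for e in one_way_dsa(base_config) if e.sign_flip}
    assert flips == {
        "reference.session_duration_min",
        "intervention.drug_cost.mydrane",
        "reference.n_instillation_sessions",
    }


def test_tornado_ranking_and_tie_break(base_config):
    entries = one_way_dsa(base_config)
    table = tornado_table(entries)
    spans = table["span"].tolist()
    assert spans == sorted(spans, reverse=True)
    # widest-uncertainty inputs are the nurse-workflow and price parameters
    assert set(table["parameter_path"].head(4)) == {
        "reference.session_duration_min",
        "intervention.drug_cost.mydrane",
        "reference.n_instillation_sessions",
        "nurse_rate",
    }
    # equal spans order lexicographically by path
    tied = [
        TornadoEntry("b.path", 1, 0, 2, -100.0, 100.0),
        TornadoEntry("a.path", 1, 0, 2, 100.0, -100.0),
    ]
    assert tornado_table(tied)["parameter_path"].tolist() == ["a.path", "b.path"]


def test_single_entry_is_ranked_first_and_empty_list_gives_empty_table():
    entry = TornadoEntry("only", 1, 0, 2, -5.0, 5.0)
    assert tornado_table([entry])["parameter_path"].tolist() == ["only"]
    assert tornado_table([]).empty


def test_sign_flip_definition_is_a_strict_straddle():
    assert TornadoEntry("x", 1, 0, 2, -1.0, 1.0).sign_flip
    assert not TornadoEntry("x", 1, 0, 2, 0.0, 1.0).sign_flip
    assert not TornadoEntry("x", 1, 0, 2, 2.0, 1.0).sign_flip


def test_sweep_runs_quickly(base_config):
    import time

    start = time.perf_counter()
    one_way_dsa(base_config)
    assert time.perf_counter() - start < 5.0


def test_plot_tornado_writes_a_file(base_config, tmp_path, base_results):
    out = tmp_path / "tornado.png"
    base_results.plot_tornado(str(out))
    assert out.exists() and out.stat().st_size > 0


def test_unresolvable_bound_is_a_configuration_error(base_config):
    cfg = copy.deepcopy(base_config)
    cfg.dsa_bounds = list(cfg.dsa_bounds) + [DsaBound("ghost", [("ghost.path", 0, 1)])]
    with pytest.raises(Exception):
        one_way_dsa(cfg)
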