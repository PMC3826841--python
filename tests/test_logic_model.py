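import json

import pytest
from hypothesis import given, settings, strategies as st

from cyclogic.engine import SimulationConfig, growth_rate, wild_type_period
from cyclogic.logic_model import (
    ModelDefinition,
    NodeDef,
    PhaseSignature,
    RuleDef,
    SchemaError,
    ValidationError,
    make_toy_model,
    model_to_dict,
    parse_model,
    toggle_module,
    write_model,
)


def test_packaged_model_has_base_plus_thirty_nodes(yeast):
    # 22-node core extended by 30 regulators
    assert len(yeast.nodes) == 52


def test_parse_write_round_trip(tmp_path, yeast):
    path = tmp_path / "m.json"
    write_model(yeast, path)
    again = parse_model(path)
    assert model_to_dict(again) == model_to_dict(yeast)


def test_canonical_write_is_byte_stable(tmp_path, ring6):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_model(ring6, p1)
    write_model(ring6, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_unresolved_node_reference_names_the_node(tmp_path):
    data = {
        "nodes": [{"name": "A", "max_level": 1, "role": "gene"}],
        "rules": [{"target": "A", "target_level": 1, "expr": ["GE", "X", 1]}],
        "start_state": {"A": 0},
    }
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(data))
    with pytest.raises(SchemaError, match="X"):
        parse_model(path)


def test_leaf_level_out_of_range_rejected():
    nodes = (NodeDef("A", 1),)
    rules = (RuleDef("A", 1, ["GE", "A", 5]),)
    model = ModelDefinition(nodes=nodes, rules=rules, start_state={"A": 0})
    with pytest.raises(SchemaError, match="out of range"):
        model.validate_static()


def test_duplicate_rule_for_target_level_rejected():
    nodes = (NodeDef("A", 1),)
    rules = (RuleDef("A", 1, ["GE", "A", 0]), RuleDef("A", 1, ["EQ", "A", 0]))
    with pytest.raises(SchemaError, match="duplicate"):
        ModelDefinition(nodes=nodes, rules=rules,
                        start_state={"A": 0}).validate_static()


def test_non_exclusive_signatures_fail_dynamic_validation():
    nodes = (NodeDef("A", 1, "state-variable"),)
    rules = (RuleDef("A", 1, ["EQ", "A", 0]),)
    sigs = (PhaseSignature("G1", ["GE", "A", 0]),
            PhaseSignature("S_G2", ["EQ", "A", 0]))  # overlap on A=0
    model = ModelDefinition(nodes=nodes, rules=rules, signatures=sigs,
                            start_state={"A": 0})
    model.validate_static()
    with pytest.raises(ValidationError, match="signature"):
        model.validate_dynamics()


def test_toggle_unknown_module_lists_available(yeast):
    with pytest.raises(KeyError, match="spindle_checkpoint"):
        toggle_module(yeast, "nonsense", True)


def test_toggle_idle_module_preserves_wild_type_period(yeast, yeast_wt_period):
    # the checkpoint stubs are quiescent without their stress inputs
    for name in yeast.module_names():
        toggled = toggle_module(yeast, name, True)
        assert wild_type_period(toggled) == yeast_wt_period


def test_module_can_block_cytokinesis():
    """A toggleable block whose rule gates the cytokinesis trigger arrests
    the oscillator when enabled."""
    from cyclogic.logic_model import ModuleBlock

    ring = make_toy_model("ring-oscillator", 6)
    # rebuild with a module that forces the pulse to die at position 3
    rules = tuple(
        RuleDef(r.target, r.target_level,
                ["AND", _as_list(r.expr), ["NOT", ["GE", "BLOCK", 1]]])
        if r.target == "R3" else r
        for r in ring.rules
    )
    blocked = ModelDefinition(
        nodes=ring.nodes, rules=rules, signatures=ring.signatures,
        start_state=ring.start_state, event_nodes=ring.event_nodes,
        modules=(ModuleBlock(
            name="blocker",
            nodes=(NodeDef("BLOCK", 1, "state-variable"),),
            rules=(RuleDef("BLOCK", 1, ["GE", "BLOCK", 0]),),
        ),),
        name="blocked-ring",
    )
    blocked.validate_static()
    cfg = SimulationConfig(n_steps=60, n_replicates=2, seed=0)
    off = growth_rate(blocked, None, cfg)
    assert off.relative_growth_rate == pytest.approx(1.0)
    on = growth_rate(toggle_module(blocked, "blocker", True), None, cfg,
                     wt_period=wild_type_period(blocked))
    assert on.arrested and on.relative_growth_rate == 0.0


def _as_list(expr):
    if isinstance(expr, tuple):
        return [_as_list(e) for e in expr]
    return expr


@pytest.mark.parametrize("size", [4, 6, 9])
def test_ring_oscillator_period_equals_size(size):
    model = make_toy_model("ring-oscillator", size)
    assert wild_type_period(model) == size


def test_toggle_toy_is_period_two(toggle2):
    assert wild_type_period(toggle2) == 2


def test_arrester_has_no_reachable_event():
    model = make_toy_model("arrester", 6)
    result = growth_rate(model, None,
                         SimulationConfig(n_steps=120, n_replicates=2, seed=0))
    assert result.arrested


def test_oversized_toy_rejected():
    with pytest.raises(ValueError, match="enumeration bound"):
        make_toy_model("ring-oscillator", 30)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(size=st.integers(min_value=4, max_value=9))
def test_toy_models_validate_and_recur(size):
    model = make_toy_model("ring-oscillator", size)
    assert model.validate_dynamics(max_period=4 * size) == size
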