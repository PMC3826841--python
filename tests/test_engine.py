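import numpy as np
import pytest

from cyclogic.dosage import DosageSpec
from cyclogic.engine import (
    CycleEvent,
    SimulationConfig,
    Trajectory,
    detect_cycles,
    growth_rate,
    simulate,
    step,
    wild_type_period,
)
from cyclogic.logic_model import ModelDefinition, NodeDef, RuleDef, \
    make_toy_model


def test_toggle_step_by_hand(toggle2):
    state = toggle2.full_start_state()          # all inverters at 1
    nxt = step(state, toggle2)
    assert nxt["T0"] == 0 and nxt["T1"] == 0
    nxt2 = step(nxt, toggle2)
    assert nxt2["T0"] == 1 and nxt2["T1"] == 1


def test_deterministic_step_is_a_function(ring6):
    state = ring6.full_start_state()
    assert step(state, ring6) == step(state, ring6)


def test_stochastic_step_requires_rng(ring6):
    with pytest.raises(ValueError):
        step(ring6.full_start_state(), ring6, DosageSpec({"R0": 0.5}))


def _trajectory(cyto_levels, mass_levels):
    nodes = ("CYTO", "MASS")
    states = np.array(list(zip(cyto_levels, mass_levels)), dtype=np.int16)
    return Trajectory(nodes, states)


def _event_model():
    nodes = (NodeDef("CYTO", 2, "event-marker"),
             NodeDef("MASS", 1, "event-marker"))
    return ModelDefinition(
        nodes=nodes, rules=(RuleDef("MASS", 1, ["GE", "MASS", 0]),),
        start_state={"CYTO": 0, "MASS": 1},
        event_nodes={"cytokinesis": "CYTO", "mass": "MASS",
                     "cytokinesis_level": 2})


def test_two_step_run_is_not_an_event():
    model = _event_model()
    traj = _trajectory([0, 2, 2, 0, 0], [1, 1, 1, 1, 1])
    assert detect_cycles(traj, model) == []


def test_three_step_run_with_mass_return_is_one_event():
    model = _event_model()
    traj = _trajectory([0, 2, 2, 2, 0, 0], [2, 2, 2, 2, 2, 1])
    events = detect_cycles(traj, model)
    assert len(events) == 1
    ev = events[0]
    assert ev.cytokinesis_run == (1, 3)
    assert ev.end_step == 5 and ev.period == 5


def test_run_open_at_trajectory_end_is_discarded():
    model = _event_model()
    traj = _trajectory([0, 2, 2, 2], [1, 1, 1, 1])
    assert detect_cycles(traj, model) == []


def test_constant_zero_trajectory_has_no_events():
    model = _event_model()
    traj = _trajectory([0] * 8, [1] * 8)
    assert detect_cycles(traj, model) == []


def test_mass_return_switch():
    model = _event_model()
    # qualifying run but mass never returns to one
    traj = _trajectory([0, 2, 2, 2, 0, 0], [2, 2, 2, 2, 2, 2])
    assert detect_cycles(traj, model, require_mass_return=True) == []
    assert len(detect_cycles(traj, model, require_mass_return=False)) == 1


def test_ring_event_count_is_floor_n_over_period():
    for size, n_steps in [(5, 57), (6, 60), (8, 100)]:
        model = make_toy_model("ring-oscillator", size)
        result = growth_rate(model, None,
                             SimulationConfig(n_steps=n_steps, n_replicates=2,
                                              seed=0))
        assert result.completed_events == n_steps // size
        assert result.relative_growth_rate == pytest.approx(1.0)


def test_wild_type_is_deterministic_across_replicates_and_seeds(ring6):
    cfg1 = SimulationConfig(n_steps=120, n_replicates=5, seed=1,
                            record_trajectory=True)
    cfg2 = SimulationConfig(n_steps=120, n_replicates=3, seed=99,
                            record_trajectory=True)
    s1 = simulate(ring6, None, cfg1)
    s2 = simulate(ring6, None, cfg2)
    assert np.array_equal(s1.trajectory.states, s2.trajectory.states)
    assert len(set(s1.event_counts)) == 1


def test_knockout_of_pacing_shortcut_halves_growth_rate():
    """A ring with a PACE-gated shortcut runs at half period with PACE on;
    deleting PACE (d = 0) restores the long way round: relative rate 0.5."""
    size = 8
    half = size // 2
    nodes = [NodeDef(f"R{i}", 1, "state-variable") for i in range(size)]
    nodes += [NodeDef("PACE", 1, "gene"),
              NodeDef("CYTO", 2, "event-marker"),
              NodeDef("MASS", 1, "event-marker")]
    rules = [RuleDef("PACE", 1, ["GE", "PACE", 0]),
             RuleDef("MASS", 1, ["GE", "MASS", 0])]
    for i in range(size):
        if i == 0:
            # shortcut from the halfway point when PACE is active
            rules.append(RuleDef("R0", 1, ["OR",
                ["GE", f"R{size-1}", 1],
                ["AND", ["GE", f"R{half-1}", 1], ["GE", "PACE", 1]]]))
        elif i == half:
            rules.append(RuleDef(f"R{half}", 1, ["AND",
                ["GE", f"R{half-1}", 1], ["NOT", ["GE", "PACE", 1]]]))
        else:
            rules.append(RuleDef(f"R{i}", 1, ["GE", f"R{i-1}", 1]))
    # cytokinesis window: last three ring positions
    rules.append(RuleDef("CYTO", 2, ["OR"] + [
        ["GE", f"R{size-3+j}", 1] for j in range(3)]))
    start = {f"R{i}": 1 if i == 1 else 0 for i in range(size)}
    start.update({"PACE": 1, "CYTO": 0, "MASS": 1})
    model = ModelDefinition(
        nodes=tuple(nodes), rules=tuple(rules), start_state=start,
        event_nodes={"cytokinesis": "CYTO", "mass": "MASS",
                     "cytokinesis_level": 2},
        name="paced-ring")
    model.validate_static()
    # wild type: shortcut active -> period = half; CYTO window unreachable?
    # the pulse jumps from R3 to R0, skipping R4..R7, so no events with PACE
    # on the *short* loop; measure period via start-state recurrence instead
    assert wild_type_period(model) == half
    cfg = SimulationConfig(n_steps=160, n_replicates=4, seed=3)
    ko = growth_rate(model, DosageSpec({"PACE": 0.0}), cfg,
                     wt_period=wild_type_period(model))
    # knockout takes the full ring: period = size = 2 * half
    assert ko.mean_period == pytest.approx(size)
    assert ko.relative_growth_rate == pytest.approx(0.5)


def test_growth_rate_reports_se_and_period_ratio(ring6):
    cfg = SimulationConfig(n_steps=240, n_replicates=80, seed=6)
    res = growth_rate(ring6, DosageSpec({"R2": 0.9}), cfg)
    assert res.se >= 0.0
    assert res.period_ratio == pytest.approx(1.0 / res.relative_growth_rate
                                             if res.relative_growth_rate else 0,
                                             rel=0.2)


def test_arrested_replicates_contribute_zero_rate():
    model = make_toy_model("ring-oscillator", 6)
    # knocking the pulse out entirely arrests every replicate
    res = growth_rate(model, DosageSpec({f"R{i}": 0.0 for i in range(6)}),
                      SimulationConfig(n_steps=100, n_replicates=8, seed=0))
    assert res.arrested and res.relative_growth_rate == 0.0
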