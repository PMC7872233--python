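import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from braflogic.logic_core import (
    ModelSyntaxError,
    ModelValidationError,
    NetworkModel,
    NodeSpec,
    UnknownNodeError,
    add_inhibitor,
    apply_perturbations,
    evaluate_expression,
    parse_expression,
    parse_model,
    serialize_model,
    target_level,
    validate_model,
)
from braflogic.simulator import InitialCondition, SimulationConfig, simulate

from conftest import make_model


@pytest.mark.parametrize(
    "expr,state,expected",
    [
        ("A & !B", {"A": 1, "B": 0}, True),
        ("A & !B", {"A": 1, "B": 1}, False),
        ("A | B", {"A": 0, "B": 0}, False),
        ("A | B", {"A": 0, "B": 1}, True),
        ("MEK:2", {"MEK": 1}, False),
        ("MEK:2", {"MEK": 2}, True),
        ("!(A | B) & C", {"A": 0, "B": 0, "C": 1}, True),
        ("1", {}, True),
        ("0", {}, False),
    ],
)
def test_expression_evaluation(expr, state, expected):
    assert evaluate_expression(parse_expression(expr), state) is expected


def test_expression_unknown_node_raises():
    with pytest.raises(UnknownNodeError):
        evaluate_expression(parse_expression("A & Q"), {"A": 1})


@pytest.mark.parametrize("bad", ["A &", "A | | B", "(A", "A @ B", "2foo"])
def test_expression_syntax_errors(bad):
    with pytest.raises(ModelSyntaxError):
        parse_expression(bad)


def test_parse_minimal_model():
    model = parse_model('{"nodes": [{"name": "A", "is_input": true}, {"name": "B"}], "rules": {"B": "A"}}')
    assert model.node("A").is_input
    assert not model.node("B").is_input
    assert len(model.nodes) == 2


def test_parse_rejects_out_of_range_literal():
    with pytest.raises(ModelValidationError):
        parse_model(
            '{"nodes": [{"name": "MEK", "max_level": 2}, {"name": "X"}],'
            ' "rules": {"MEK": ["X", "X"], "X": "MEK:3"}}'
        )


def test_parse_rejects_undeclared_reference():
    with pytest.raises(UnknownNodeError):
        parse_model('{"nodes": [{"name": "A"}], "rules": {"A": "GHOST"}}')


def test_node_spec_invariants():
    with pytest.raises(ModelValidationError):
        NodeSpec("A", max_level=0)
    with pytest.raises(ModelValidationError):
        NodeSpec("A", rate_up=0.0)
    with pytest.raises(ModelValidationError):
        NodeSpec("not an identifier!")


def test_duplicate_node_names_rejected():
    with pytest.raises(ModelValidationError):
        NetworkModel(nodes=[NodeSpec("A"), NodeSpec("A")])


def test_round_trip_serialization(braf, mv_model):
    for model in (braf, mv_model):
        again = parse_model(serialize_model(model))
        assert serialize_model(again) == serialize_model(model)
        assert again.node_names == model.node_names


@pytest.mark.parametrize(
    "state,expected",
    [({"U": 0, "V": 1, "M": 0}, 1), ({"U": 1, "V": 0, "M": 0}, 2), ({"U": 0, "V": 0, "M": 0}, 0)],
)
def test_target_level_multivalued(mv_model, state, expected):
    # target is the highest satisfied level: V alone reaches 1, U reaches 2
    assert target_level(mv_model, "M", state) == expected


def test_target_level_input_holds(mv_model):
    assert target_level(mv_model, "U", {"U": 1, "V": 0, "M": 0}) == 1


def test_apply_perturbations_forces_target_everywhere(mv_model):
    forced = apply_perturbations(mv_model, {"M": 2})
    for u in (0, 1):
        for v in (0, 1):
            for m in (0, 1, 2):
                assert target_level(forced, "M", {"U": u, "V": v, "M": m}) == 2
    # original untouched
    assert target_level(mv_model, "M", {"U": 0, "V": 0, "M": 0}) == 0


def test_apply_perturbations_is_idempotent(mv_model):
    once = apply_perturbations(mv_model, {"M": 1})
    twice = apply_perturbations(once, {"M": 1})
    assert serialize_model(once) == serialize_model(twice)


def test_empty_perturbation_is_identity(mv_model):
    assert serialize_model(apply_perturbations(mv_model, {})) == serialize_model(mv_model)


def test_perturbation_level_out_of_range(mv_model):
    with pytest.raises(ModelValidationError):
        apply_perturbations(mv_model, {"M": 3})


def test_forced_multivalued_node_holds_level_in_simulation(mv_model):
    forced = apply_perturbations(mv_model, {"M": 2})
    result = simulate(forced, None, SimulationConfig(n_trajectories=200, seed=3))
    col = result.node_column("M")
    assert (result.final_states[:, col] == 2).all()
    assert np.allclose(result.mean_activation["M"], 1.0)


def test_add_inhibitor_rejects_bad_targets(chain_model):
    with pytest.raises(ModelValidationError):
        add_inhibitor(chain_model, "A")  # input
    with pytest.raises(ModelValidationError):
        add_inhibitor(chain_model, "B", "A")  # name collision


def test_inhibitor_on_forces_target_off(chain_model):
    inhibited = add_inhibitor(chain_model, "B", "drug")
    ic = InitialCondition({"A": 1.0, "B": 0.0, "drug": 1.0})
    result = simulate(inhibited, ic, SimulationConfig(n_trajectories=500, t_end=20.0, seed=0))
    assert result.final_activation("B") == 0.0


def test_inhibitor_off_is_bit_identical_to_original(chain_model):
    config = SimulationConfig(n_trajectories=500, seed=11)
    base = simulate(chain_model, InitialCondition({"A": 1.0}), config)
    inhibited = add_inhibitor(chain_model, "B", "drug")
    off = simulate(inhibited, InitialCondition({"A": 1.0, "drug": 0.0}), config)
    n = len(chain_model.node_names)
    assert np.array_equal(base.final_states, off.final_states[:, :n])
    assert np.allclose(
        base.mean_activation.values, off.mean_activation.values[:, :n]
    )


def test_inhibitor_off_restores_target_levels_exhaustively(mv_model):
    inhibited = add_inhibitor(mv_model, "M", "drug")
    for u in (0, 1):
        for v in (0, 1):
            for m in (0, 1, 2):
                state = {"U": u, "V": v, "M": m, "drug": 0}
                assert target_level(inhibited, "M", state) == target_level(
                    mv_model, "M", {"U": u, "V": v, "M": m}
                )


def test_add_inhibitor_overrides_forced_node(chain_model):
    forced = apply_perturbations(chain_model, {"B": 1})
    inhibited = add_inhibitor(forced, "B", "drug")
    assert "B" not in inhibited.forced
    assert inhibited.init_overrides["B"] == 1
    result = simulate(
        inhibited,
        InitialCondition({"A": 0.0, "drug": 1.0}),
        SimulationConfig(n_trajectories=300, t_end=20.0, seed=1),
    )
    assert result.final_activation("B") == 0.0


def test_validate_model_passes_on_fixture(braf):
    assert validate_model(braf).ok


def test_validate_model_flags_nesting_violation():
    model = make_model(
        {
            "nodes": [{"name": "A", "is_input": True}, {"name": "M", "max_level": 2}],
            "rules": {"M": ["A", "!A"]},  # level 2 does not imply level 1
        }
    )
    report = validate_model(model)
    assert any(f.kind == "nesting" for f in report.findings)


def test_validate_model_flags_dangling_reference():
    model = NetworkModel(
        nodes=[NodeSpec("A")],
        rules={"A": [parse_expression("GHOST")]},
    )
    report = validate_model(model)
    assert any(f.kind == "dangling-reference" for f in report.findings)


# --- property: expression round trip ---------------------------------------

_names = st.sampled_from(["A", "B", "C2", "node_x"])


@st.composite
def expressions(draw, depth=0):
    if depth > 3 or draw(st.booleans()):
        if draw(st.booleans()):
            return f"{draw(_names)}:{draw(st.integers(1, 3))}"
        return draw(_names)
    op = draw(st.sampled_from(["&", "|", "!"]))
    if op == "!":
        return f"!({draw(expressions(depth + 1))})"
    return f"({draw(expressions(depth + 1))}) {op} ({draw(expressions(depth + 1))})"


@given(expressions())
def test_expression_parse_is_stable(text):
    """Parsing the printed form of a parsed expression is a fixed point."""
    expr = parse_expression(text)
    assert parse_expression(str(expr)) == expr
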