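import math

import numpy as np
import pandas as pd
import pytest

from braflogic.logic_core import ModelValidationError, target_level
from braflogic.personalization import (
    CellLineProfile,
    FunctionalAnnotation,
    GeneNodeMap,
    MutationRecord,
    expression_to_node_values,
    interpret_mutations,
    load_default_annotations,
    load_default_gene_node_map,
    normalize_expression,
    personalize,
    personalize_continuous,
    personalize_discrete,
    rate_from_value,
)
from braflogic.simulator import SimulationConfig, simulate


@pytest.fixture(scope="module")
def annotations():
    return load_default_annotations()


@pytest.fixture(scope="module")
def gene_map():
    return load_default_gene_node_map()


# --- mutation interpretation -------------------------------------------------


def test_v600e_is_gain_of_function(annotations, gene_map):
    records = [MutationRecord("HT-29x", "BRAF", "V600E")]
    effects = interpret_mutations(records, annotations, gene_map)
    assert effects == {"HT-29x": {"BRAF": "GOF"}}


def test_truncating_class_matches_frameshift_and_nonsense(annotations):
    assert annotations.effect_of("TP53", "R213*") == "LOF"
    assert annotations.effect_of("PTEN", "K128fs") == "LOF"
    assert annotations.effect_of("BRAF", "R509fs") is None  # no truncating row


def test_unannotated_mutations_are_dropped(annotations, gene_map):
    records = [MutationRecord("line1", "RPS6KB2", "G61fs"), MutationRecord("line1", "BRAF", "P403L")]
    assert interpret_mutations(records, annotations, gene_map) == {}


def test_conflicting_effects_raise():
    annot = FunctionalAnnotation([("G", "A1X", "GOF"), ("G", "truncating", "LOF")])
    gmap = GeneNodeMap({"G": "N"})
    records = [MutationRecord("c", "G", "A1X"), MutationRecord("c", "G", "Q9fs")]
    with pytest.raises(ModelValidationError):
        interpret_mutations(records, annot, gmap)


def test_empty_record_list(annotations, gene_map):
    assert interpret_mutations([], annotations, gene_map) == {}


def test_ras_family_maps_many_to_one(gene_map):
    assert {gene_map.node_for(g) for g in ("NRAS", "KRAS", "HRAS")} == {"RAS"}


# --- expression normalization ------------------------------------------------


def test_minmax_normalization():
    matrix = pd.DataFrame({"s1": [2.0, 5.0], "s2": [4.0, 5.0], "s3": [6.0, 5.0]}, index=["g1", "g2"])
    norm = normalize_expression(matrix)
    assert list(norm.loc["g1"]) == [0.0, 0.5, 1.0]
    assert list(norm.loc["g2"]) == [0.5, 0.5, 0.5]  # constant gene


def test_normalization_rejects_bad_input():
    with pytest.raises(ValueError):
        normalize_expression(pd.DataFrame({"s1": [1.0]}, index=["g"]))
    with pytest.raises(ModelValidationError):
        normalize_expression(pd.DataFrame({"s1": [-1.0], "s2": [1.0]}, index=["g"]).T.T)


def test_monotone_transform_preserves_ranking():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.gamma(2.0, 2.0, size=(5, 30)))
    transformed = np.log1p(raw)
    a = normalize_expression(raw)
    b = normalize_expression(transformed)
    for g in raw.index:
        assert (a.loc[g].rank() == b.loc[g].rank()).all()


def test_rna_excluded_genes_are_not_projected(gene_map):
    matrix = pd.DataFrame(
        {"c1": [1.0, 1.0, 1.0], "c2": [2.0, 2.0, 2.0]},
        index=["BRAF", "ATM", "RAF1"],
    )
    values = expression_to_node_values(normalize_expression(matrix), gene_map, "c2")
    assert "BRAF" not in values and "ATM" not in values
    assert values["CRAF"] == 1.0


# --- rate mapping ------------------------------------------------------------


def test_rate_from_value_neutral_midpoint():
    assert rate_from_value(0.5) == (1.0, 1.0)


def test_rate_from_value_extremes():
    up, down = rate_from_value(1.0, amplification=100.0)
    assert up == pytest.approx(100.0)
    assert down == pytest.approx(0.01)


def test_rate_from_value_symmetry():
    for x in (0.1, 0.3, 0.8):
        u1, d1 = rate_from_value(x)
        u2, d2 = rate_from_value(1.0 - x)
        assert u1 == pytest.approx(d2) and d1 == pytest.approx(u2)
        assert u1 * d1 == pytest.approx(1.0)


def test_rate_from_value_rejects_out_of_range():
    with pytest.raises(ModelValidationError):
        rate_from_value(1.2)


# --- personalization strategies ---------------------------------------------


def test_discrete_personalization_forces_nodes(braf):
    profile = CellLineProfile(id="c", effects={"BRAF": "GOF", "PTEN": "LOF"})
    pmodel = personalize_discrete(braf, profile)
    state = {n: 0 for n in braf.node_names}
    assert target_level(pmodel.model, "BRAF", state) == 1
    assert target_level(pmodel.model, "PTEN", {**state, "p53": 1}) == 0
    # simulation holds the forced levels at every reported time point
    result = simulate(pmodel.model, pmodel.initial_condition, SimulationConfig(n_trajectories=300, seed=2))
    assert np.allclose(result.mean_activation["BRAF"], 1.0)
    assert np.allclose(result.mean_activation["PTEN"], 0.0)


def test_discrete_with_no_effects_is_generic(braf):
    from braflogic.logic_core import serialize_model

    pmodel = personalize_discrete(braf, CellLineProfile(id="c"))
    assert serialize_model(pmodel.model) == serialize_model(braf)


def test_neutral_continuous_profile_reproduces_generic_bit_identically(braf):
    profile = CellLineProfile(
        id="c", expression={n: 0.5 for n in braf.node_names}
    )
    pmodel = personalize_continuous(braf, profile)
    config = SimulationConfig(n_trajectories=2000, seed=23)
    base = simulate(braf, "generic", config)
    pers = simulate(pmodel.model, pmodel.initial_condition, config)
    assert np.array_equal(base.final_states, pers.final_states)
    assert np.array_equal(base.mean_activation.values, pers.mean_activation.values)


def test_continuous_activation_monotone_in_x_toggle_closed_form(toggle_model):
    """Isolated unregulated node: t_end activation follows the 2-state closed form."""
    t_end = 2.0
    activations = []
    for x in (0.0, 0.25, 0.5, 0.75, 1.0):
        profile = CellLineProfile(id=f"x{x}", expression={"A": x})
        pmodel = personalize_continuous(toggle_model, profile)
        result = simulate(
            pmodel.model, pmodel.initial_condition,
            SimulationConfig(n_trajectories=20_000, t_end=t_end, seed=31),
        )
        observed = result.final_activation("A")
        ku, kd = rate_from_value(x)
        stationary = ku / (ku + kd)
        expected = stationary + (x - stationary) * math.exp(-(ku + kd) * t_end)
        se = math.sqrt(max(expected * (1 - expected), 1e-6) / 20_000)
        assert abs(observed - expected) < 4 * se
        activations.append(observed)
    assert activations == sorted(activations)


def test_input_node_initial_activation_follows_expression(braf):
    profile = CellLineProfile(id="c", expression={"SOX10": 1.0})
    pmodel = personalize_continuous(braf, profile)
    assert pmodel.initial_condition.activation("SOX10") == 1.0


def test_mutation_dominates_rna_in_combined_strategy(braf):
    profile = CellLineProfile(
        id="c", effects={"BRAF": "GOF"}, expression={"BRAF": 0.05, "CRAF": 0.9}
    )
    pmodel = personalize(braf, profile, "mutations+rna")
    # forced node: no rate override, held at 1 in simulation
    assert "BRAF" not in pmodel.rate_overrides
    spec = pmodel.model.node("BRAF")
    assert (spec.rate_up, spec.rate_down) == (1.0, 1.0)
    result = simulate(pmodel.model, pmodel.initial_condition, SimulationConfig(n_trajectories=300, seed=4))
    assert np.allclose(result.mean_activation["BRAF"], 1.0)
    # the RNA layer survives on non-forced nodes
    assert pmodel.rate_overrides["CRAF"][0] == pytest.approx(100.0 ** 0.8)


def test_rna_strategy_equals_continuous(braf):
    from braflogic.logic_core import serialize_model

    profile = CellLineProfile(id="c", expression={"CRAF": 0.8})
    a = personalize(braf, profile, "rna")
    b = personalize_continuous(braf, profile)
    assert serialize_model(a.model) == serialize_model(b.model)
    assert a.initial_condition == b.initial_condition


def test_unknown_strategy_rejected(braf):
    with pytest.raises(ValueError):
        personalize(braf, CellLineProfile(id="c"), "proteomics")
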