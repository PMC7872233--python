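import numpy as np
import pandas as pd
import pytest

from braflogic.personalization import CellLineProfile, personalize, personalize_discrete
from braflogic.sensitivity_pipeline import (
    cohort_feature_table,
    correlate,
    fit_baseline,
    normalize_scores,
    permutation_importance,
    profiles_from_cohort,
    run_inhibition_experiment,
    run_validation,
)
from braflogic.simulator import SimulationConfig
from braflogic.synthetic_cohort import CohortConfig, generate_cohort, generate_sensitivities

from conftest import make_model


# --- score normalization and correlation ------------------------------------


def test_normalize_scores_minmax():
    assert normalize_scores([0.2, 0.6, 1.0]) == pytest.approx([0.0, 0.5, 1.0])


def test_normalize_scores_constant_vector():
    assert list(normalize_scores([0.7, 0.7, 0.7])) == [0.5, 0.5, 0.5]


def test_normalize_scores_empty_raises():
    with pytest.raises(ValueError):
        normalize_scores([])


def test_normalize_scores_preserves_order():
    rng = np.random.default_rng(0)
    v = rng.normal(size=50)
    assert (np.argsort(normalize_scores(v)) == np.argsort(v)).all()


def test_correlate_identity_and_negation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert correlate(x, x)[0] == pytest.approx(1.0)
    assert correlate(x, -x + 7)[0] == pytest.approx(-1.0)


def test_correlate_matches_textbook_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 10.0])
    # direct product-moment computation, independent of the implementation path
    r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    r, p, n = correlate(x, y)
    assert r == pytest.approx(r_hand)
    assert n == 5 and 0 < p < 1


def test_correlate_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        correlate([1.0, 2.0], [1.0, 2.0])  # n < 3
    with pytest.raises(ValueError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero variance


# --- inhibition experiments --------------------------------------------------


def test_disconnected_target_leaves_phenotype_unchanged():
    model = make_model(
        {
            "nodes": [{"name": "I", "is_input": True}, {"name": "X"}, {"name": "P"}],
            "rules": {"X": "1", "P": "I"},
            "phenotypes": {"Proliferation": "P"},
        }
    )
    pmodel = personalize_discrete(model, CellLineProfile(id="c"))
    exp = run_inhibition_experiment(pmodel, "X", SimulationConfig(n_trajectories=8000, seed=3))
    se = 3 * np.sqrt(0.25 / 8000) / max(exp.untreated_score, 1e-9)
    assert abs(exp.ratio - 1.0) < 3 * se


def test_braf_inhibition_reduces_proliferation(braf):
    pmodel = personalize_discrete(braf, CellLineProfile(id="generic"))
    exp = run_inhibition_experiment(pmodel, "BRAF", SimulationConfig(n_trajectories=4000, seed=5))
    assert exp.inhibited_score < exp.untreated_score
    assert exp.ratio < 1.0


def test_pi3k_activation_confers_resistance_to_braf_inhibition(braf):
    """PI3K hyperactivation sustains proliferation under BRAF inhibition:
    the inhibited phenotype score stays higher than without the lesion."""
    config = SimulationConfig(n_trajectories=4000, seed=5)
    plain = run_inhibition_experiment(
        personalize_discrete(braf, CellLineProfile(id="a", effects={"BRAF": "GOF"})),
        "BRAF",
        config,
    )
    with_pi3k = run_inhibition_experiment(
        personalize_discrete(
            braf, CellLineProfile(id="b", effects={"BRAF": "GOF", "PI3K": "GOF"})
        ),
        "BRAF",
        config,
    )
    assert with_pi3k.inhibited_score > plain.inhibited_score


def test_undefined_ratio_is_flagged():
    model = make_model(
        {
            "nodes": [{"name": "X"}, {"name": "P"}],
            "rules": {"X": "1", "P": "0"},
            "phenotypes": {"Proliferation": "P"},
        }
    )
    pmodel = personalize_discrete(model, CellLineProfile(id="c"))
    exp = run_inhibition_experiment(pmodel, "X", SimulationConfig(n_trajectories=200, seed=1))
    assert exp.ratio_undefined and exp.ratio == 1.0


def test_inhibition_rejects_input_target(chain_model):
    pmodel = personalize_discrete(chain_model, CellLineProfile(id="c"))
    with pytest.raises(ValueError):
        run_inhibition_experiment(pmodel, "A", SimulationConfig(n_trajectories=10, seed=0))


# --- cohort-level validation -------------------------------------------------


@pytest.fixture(scope="module")
def small_cohort():
    config = CohortConfig(n_melanoma=15, n_crc=15, seed=11)
    cohort = generate_cohort(config)
    sens = generate_sensitivities(cohort, config)
    return cohort, sens


def test_profiles_interpret_cohort_tables(small_cohort):
    cohort, _ = small_cohort
    profiles = profiles_from_cohort(cohort)
    assert [p.id for p in profiles] == cohort.cell_lines
    braf_mut = set(cohort.mutations.query("gene == 'BRAF'")["cell_line"])
    for p in profiles:
        if p.id in braf_mut:
            assert p.effects.get("BRAF") == "GOF"
        assert all(0.0 <= x <= 1.0 for x in p.expression.values())
        assert "ATM" not in p.expression  # mutation-only genes carry no RNA layer


def test_run_validation_produces_signed_correlations(braf, small_cohort):
    cohort, sens = small_cohort
    results = run_validation(
        braf, cohort, sens, ["mutations"], ["BRAF"], SimulationConfig(n_trajectories=1000, seed=5)
    )
    by_metric = {v.metric: v for v in results}
    assert set(by_metric) == {"auc", "scaled_bayes_factor"}
    assert by_metric["auc"].n == len(cohort.cell_lines)
    assert by_metric["auc"].r > 0 > by_metric["scaled_bayes_factor"].r


def test_combined_strategy_keeps_mutation_signal(braf):
    """At the documented cohort conditions, adding RNA does not erode the
    mutation-only correlation (it sharpens the within-BRAF-mutant ranking)."""
    config = CohortConfig(seed=0)
    cohort = generate_cohort(config)
    sens = generate_sensitivities(cohort, config)
    results = run_validation(
        braf, cohort, sens, ["mutations", "mutations+rna"], ["BRAF"],
        SimulationConfig(n_trajectories=1000, seed=5),
    )
    r = {(v.strategy, v.metric): v.r for v in results}
    assert r[("mutations+rna", "auc")] >= r[("mutations", "auc")] - 0.05


# --- randomized-tree baseline ------------------------------------------------


def test_baseline_learns_deterministic_signal():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, size=400).astype(float)
    features = pd.DataFrame({"signal": x, "noise": rng.normal(size=400)})
    fitted = fit_baseline(features, 3.0 * x + 1.0, n_trees=200, seed=1)
    assert fitted.explained_variance > 0.9


def test_baseline_on_pure_noise_explains_nothing():
    rng = np.random.default_rng(1)
    evs = []
    for seed in range(10):
        features = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        evs.append(fit_baseline(features, rng.normal(size=100), n_trees=100, seed=seed).explained_variance)
    assert np.mean(evs) <= 0.1


def test_baseline_seed_determinism():
    rng = np.random.default_rng(2)
    features = pd.DataFrame(rng.normal(size=(60, 4)))
    y = features.iloc[:, 0] + rng.normal(scale=0.1, size=60)
    a = fit_baseline(features, y, n_trees=50, seed=3).explained_variance
    b = fit_baseline(features, y, n_trees=50, seed=3).explained_variance
    assert a == b


def test_permutation_importance_identifies_planted_feature():
    rng = np.random.default_rng(4)
    features = pd.DataFrame(
        {"planted": rng.normal(size=300), "n1": rng.normal(size=300), "n2": rng.normal(size=300)}
    )
    y = 2.0 * features["planted"] + rng.normal(scale=0.3, size=300)
    fitted = fit_baseline(features, y, n_trees=200, seed=5)
    importances = permutation_importance(fitted, features, y, seed=6)
    assert importances.idxmax() == "planted"
    assert abs(importances["n1"]) < 0.1


def test_braf_status_dominates_drug_sensitivity_prediction(braf, small_cohort):
    cohort, sens = small_cohort
    features = cohort_feature_table(cohort)
    auc = sens.query("metric == 'auc'").set_index("cell_line")["value"].loc[cohort.cell_lines]
    fitted = fit_baseline(features, auc, n_trees=300, seed=7)
    importances = permutation_importance(fitted, features, auc, seed=8)
    assert importances.idxmax() == "mut_BRAF"
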