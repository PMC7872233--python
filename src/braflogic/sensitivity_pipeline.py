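"""In-silico inhibition experiments and cohort-level validation.

For every cell line, the personalized model is simulated twice: untreated,
and with an inhibitor node grafted onto the target (the inhibitor, held
active, makes the target's rule unsatisfiable so the node decays to 0).
The ratio of the Proliferation phenotype score with inhibition over the
score without it is the in-silico sensitivity proxy; ratios are min-max
normalized across the cohort and correlated (Pearson) against experimental
sensitivity metrics: drug AUC (low = sensitive, so informative models give
a positive correlation) and CRISPR scaled Bayes factors (high = sensitive:
negative correlation).

A randomized-tree ensemble with out-of-bag performance and permutation
variable importance is provided as a knowledge-free learning baseline.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .logic_core import NetworkModel, add_inhibitor
from .personalization import (
    CellLineProfile,
    FunctionalAnnotation,
    GeneNodeMap,
    MutationRecord,
    PersonalizedModel,
    expression_to_node_values,
    interpret_mutations,
    load_default_annotations,
    load_default_gene_node_map,
    normalize_expression,
    personalize,
)
from .simulator import SimulationConfig, phenotype_score, simulate
from .synthetic_cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "InhibitionExperiment",
    "ValidationResult",
    "BaselineResult",
    "profiles_from_cohort",
    "run_inhibition_experiment",
    "normalize_scores",
    "correlate",
    "run_validation",
    "fit_baseline",
    "permutation_importance",
    "cohort_feature_table",
]


@dataclass
class InhibitionExperiment:
    """Result of one treated-vs-untreated simulation pair."""

    cell_line: str
    target: str
    untreated_score: float
    inhibited_score: float
    ratio: float
    ratio_undefined: bool = False


@dataclass
class ValidationResult:
    """Correlation of normalized in-silico scores with one sensitivity metric."""

    strategy: str
    target: str
    metric: str
    records: pd.DataFrame  # cell_line, ratio, score, sensitivity
    r: float
    p_value: float
    n: int
    n_dropped: int = 0


@dataclass
class BaselineResult:
    """Out-of-bag performance of the randomized-tree baseline."""

    explained_variance: float
    feature_names: list[str]
    model: RandomForestRegressor = field(repr=False)


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------


def profiles_from_cohort(
    cohort: Cohort,
    annotations: FunctionalAnnotation | None = None,
    gene_map: GeneNodeMap | None = None,
) -> list[CellLineProfile]:
    """Interpret a cohort's omics tables into per-cell-line profiles.

    Mutations go through the functional-annotation lookup; expression is
    gene-wise min-max normalized across the cohort and projected onto model
    nodes through the gene-node map.
    """
    annotations = annotations or load_default_annotations()
    gene_map = gene_map or load_default_gene_node_map()
    records = [
        MutationRecord(r.cell_line, r.gene, r.protein_change)
        for r in cohort.mutations.itertuples(index=False)
    ]
    effects = interpret_mutations(records, annotations, gene_map)
    normalized = normalize_expression(cohort.expression)
    tissues = dict(zip(cohort.samples["cell_line"], cohort.samples["tissue"]))
    profiles = []
    for cid in cohort.cell_lines:
        profiles.append(
            CellLineProfile(
                id=cid,
                tissue=tissues.get(cid, "other"),
                effects=effects.get(cid, {}),
                expression=expression_to_node_values(normalized, gene_map, cid),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Inhibition experiments
# ---------------------------------------------------------------------------


def _arm_seed(base_seed: int, cell_line: str, target: str, arm: str) -> int:
    """Deterministic per-(cell line, target, arm) seed, independent of order."""
    key = zlib.crc32(f"{cell_line}|{target}|{arm}".encode())
    return int(np.random.SeedSequence([base_seed, key]).generate_state(1)[0] % 2**31)


def run_inhibition_experiment(
    pmodel: PersonalizedModel,
    target: str,
    config: SimulationConfig,
    phenotype: str = "Proliferation",
) -> InhibitionExperiment:
    """Simulate a personalized model with and without inhibition of ``target``.

    Both arms share the configuration; their seeds are split
    deterministically from ``config.seed``.  A cell line whose untreated
    phenotype score is 0 cannot be further inhibited: its ratio is reported
    as 1.0 with the ``ratio_undefined`` flag set.
    """
    model = pmodel.model
    if model.node(target).is_input:
        raise ValueError(f"cannot run an inhibition experiment on input node {target}")
    cell = pmodel.cell_line or "cell"
    untreated = simulate(
        model,
        pmodel.initial_condition,
        config.with_seed(_arm_seed(config.seed, cell, target, "untreated")),
    )
    inhibitor = f"anti_{target}"
    treated_model = add_inhibitor(model, target, inhibitor)
    treated_ic = pmodel.initial_condition.updated({inhibitor: 1.0})
    treated = simulate(
        treated_model,
        treated_ic,
        config.with_seed(_arm_seed(config.seed, cell, target, "treated")),
    )
    u = phenotype_score(untreated, phenotype)
    t = phenotype_score(treated, phenotype)
    if u == 0.0:
        logger.warning(
            "%s: untreated %s score is 0; inhibition ratio undefined, reported as 1.0",
            cell,
            phenotype,
        )
        return InhibitionExperiment(cell, target, u, t, 1.0, ratio_undefined=True)
    return InhibitionExperiment(cell, target, u, t, t / u)


def normalize_scores(ratios: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Min-max normalize a cohort's ratios to [0,1]; a constant vector maps to 0.5."""
    v = np.asarray(ratios, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty score vector")
    span = v.max() - v.min()
    if span == 0:
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def correlate(
    scores: np.ndarray | pd.Series, sensitivities: np.ndarray | pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation with two-sided p-value from the t transform."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(sensitivities, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score and sensitivity vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in scores or sensitivities")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------


def run_validation(
    model: NetworkModel,
    cohort: Cohort,
    sensitivities: pd.DataFrame,
    strategies: list[str],
    targets: list[str],
    config: SimulationConfig,
    annotations: FunctionalAnnotation | None = None,
    gene_map: GeneNodeMap | None = None,
    amplification: float = 100.0,
) -> list[ValidationResult]:
    """Personalize, inhibit and correlate for every strategy x target x metric.

    ``sensitivities`` is a tidy table with columns cell_line, target, metric,
    value.  Cell lines without a sensitivity entry are dropped from the
    corresponding correlation with a logged count.
    """
    profiles = profiles_from_cohort(cohort, annotations, gene_map)
    results: list[ValidationResult] = []
    for strategy in strategies:
        pmodels = [personalize(model, prof, strategy, amplification) for prof in profiles]
        for target in targets:
            experiments = [
                run_inhibition_experiment(pm, target, config) for pm in pmodels
            ]
            ratios = pd.DataFrame(
                {
                    "cell_line": [e.cell_line for e in experiments],
                    "ratio": [e.ratio for e in experiments],
                }
            )
            ratios["score"] = normalize_scores(ratios["ratio"])
            subset = sensitivities[sensitivities["target"] == target]
            for metric, group in subset.groupby("metric"):
                merged = ratios.merge(
                    group[["cell_line", "value"]], on="cell_line", how="inner"
                ).rename(columns={"value": "sensitivity"})
                n_dropped = len(ratios) - len(merged)
                if n_dropped:
                    logger.info(
                        "%s/%s/%s: dropped %d cell lines without sensitivity data",
                        strategy,
                        target,
                        metric,
                        n_dropped,
                    )
                r, p, n = correlate(merged["score"], merged["sensitivity"])
                results.append(
                    ValidationResult(
                        strategy=strategy,
                        target=target,
                        metric=str(metric),
                        records=merged,
                        r=r,
                        p_value=p,
                        n=n,
                        n_dropped=n_dropped,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# Randomized-tree baseline
# ---------------------------------------------------------------------------


def cohort_feature_table(cohort: Cohort) -> pd.DataFrame:
    """Mutation statuses and normalized expression as a learning feature table."""
    ids = cohort.cell_lines
    features = pd.DataFrame(index=ids)
    mutated = cohort.mutations.groupby("gene")["cell_line"].apply(set)
    for gene in ("BRAF", "NRAS", "KRAS", "TP53", "PTEN", "PIK3CA"):
        members = mutated.get(gene, set())
        features[f"mut_{gene}"] = [float(c in members) for c in ids]
    norm = normalize_expression(cohort.expression)
    for gene in norm.index:
        features[f"rna_{gene}"] = norm.loc[gene, ids].to_numpy()
    return features


def fit_baseline(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> BaselineResult:
    """Fit a bootstrap ensemble of randomized regression trees.

    Performance is the out-of-bag explained variance
    ``1 - MSE_oob / Var(target)``.
    """
    y = np.asarray(target, dtype=float)
    if y.size < 20:
        raise ValueError("baseline needs at least 20 samples")
    if np.var(y) == 0:
        raise ValueError("constant target")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(features.to_numpy(), y)
    return BaselineResult(
        explained_variance=float(model.oob_score_),
        feature_names=list(features.columns),
        model=model,
    )


def permutation_importance(
    fitted: BaselineResult,
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Performance drop when one feature's values are permuted across samples.

    ``importance(f) = R2(original) - mean over permutations of R2(f shuffled)``.
    """
    y = np.asarray(target, dtype=float)
    X = features.to_numpy().copy()
    rng = np.random.default_rng(seed)
    base = fitted.model.score(X, y)
    importances = {}
    for j, name in enumerate(fitted.feature_names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - fitted.model.score(Xp, y))
        importances[name] = float(np.mean(drops))
    return pd.Series(importances).sort_values(ascending=False)
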