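"""Omics-driven transformation of the generic model into per-cell-line models.

Two complementary strategies, applied per cell line:

* **Discrete (mutations).**  Mutations annotated as gain-of-function force
  the corresponding node to its maximum level for the whole simulation;
  loss-of-function mutations force it to 0.  Mutations without a functional
  annotation are dropped.
* **Continuous (RNA).**  Gene expression, min-max normalized per gene across
  the cohort to ``x in [0,1]``, sets the node's initial activation
  probability to ``x`` and skews its transition rates: ``rate_up =
  A^(2x-1)``, ``rate_down = A^(1-2x)`` with amplification ``A`` (default
  100), so ``x = 0.5`` is exactly neutral and the geometric mean of the two
  rates is always 1.

In the combined strategy the continuous layer is applied first and mutation
forcing overrides it on the forced nodes: a hard genetic lesion dominates a
soft expression readout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .logic_core import (
    ModelValidationError,
    NetworkModel,
    NodeSpec,
    UnknownNodeError,
    apply_perturbations,
)
from .simulator import InitialCondition

__all__ = [
    "MutationRecord",
    "FunctionalAnnotation",
    "GeneNodeMap",
    "CellLineProfile",
    "PersonalizedModel",
    "STRATEGIES",
    "load_default_annotations",
    "load_default_gene_node_map",
    "interpret_mutations",
    "normalize_expression",
    "expression_to_node_values",
    "personalize_discrete",
    "rate_from_value",
    "personalize_continuous",
    "personalize",
]

STRATEGIES = ("mutations", "rna", "mutations+rna")

GOF = "GOF"
LOF = "LOF"


@dataclass(frozen=True)
class MutationRecord:
    cell_line: str
    gene: str
    protein_change: str

    def __post_init__(self) -> None:
        if not (self.cell_line and self.gene and self.protein_change):
            raise ValueError("mutation record fields must be non-empty")


def _is_truncating(protein_change: str) -> bool:
    """Nonsense/frameshift-style changes, e.g. ``R213*`` or ``R130fs``."""
    return protein_change.endswith("*") or "fs" in protein_change


class FunctionalAnnotation:
    """Lookup of (gene, protein change) -> GOF/LOF effect.

    Rows carry either an exact protein change or the wildcard class
    ``truncating`` matching nonsense/frameshift changes.
    """

    def __init__(self, rows: list[tuple[str, str, str]]):
        self._exact: dict[tuple[str, str], str] = {}
        self._truncating: dict[str, str] = {}
        for gene, change, effect in rows:
            if effect not in (GOF, LOF):
                raise ValueError(f"effect must be GOF or LOF, got {effect!r}")
            if change == "truncating":
                prev = self._truncating.get(gene)
                if prev is not None and prev != effect:
                    raise ValueError(f"conflicting effects for {gene} truncating")
                self._truncating[gene] = effect
            else:
                key = (gene, change)
                prev = self._exact.get(key)
                if prev is not None and prev != effect:
                    raise ValueError(f"conflicting effects for {gene} {change}")
                self._exact[key] = effect

    @classmethod
    def from_tsv(cls, text: str) -> "FunctionalAnnotation":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        required = {"gene", "protein_change", "effect"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        return cls(list(df[["gene", "protein_change", "effect"]].itertuples(index=False, name=None)))

    def effect_of(self, gene: str, protein_change: str) -> str | None:
        effect = self._exact.get((gene, protein_change))
        if effect is not None:
            return effect
        if _is_truncating(protein_change):
            return self._truncating.get(gene)
        return None


class GeneNodeMap:
    """Many-to-one mapping from gene symbols to model nodes.

    ``rna_genes`` marks the genes whose transcript abundance is accepted as
    a proxy for node activity in continuous personalization.  Genes can be
    mapped for mutation interpretation only (``use_rna = 0`` in the TSV):
    in the packaged map this covers BRAF, whose activation is driven by the
    V600 mutation rather than expression dosage, and the DNA-damage sensors
    ATM/TP53, whose activity is post-translationally controlled.
    """

    def __init__(self, mapping: dict[str, str], rna_genes: set[str] | None = None):
        self.mapping = dict(mapping)
        self.rna_genes = set(mapping) if rna_genes is None else set(rna_genes)

    @classmethod
    def from_tsv(cls, text: str) -> "GeneNodeMap":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        if not {"gene", "node"}.issubset(df.columns):
            raise ValueError("gene-node map needs columns gene, node")
        mapping = dict(zip(df["gene"], df["node"]))
        if "use_rna" in df.columns:
            rna = {g for g, flag in zip(df["gene"], df["use_rna"]) if flag == "1"}
        else:
            rna = set(mapping)
        return cls(mapping, rna)

    def node_for(self, gene: str) -> str | None:
        return self.mapping.get(gene)

    def genes_for(self, node: str) -> list[str]:
        return [g for g, n in self.mapping.items() if n == node]

    def nodes(self) -> set[str]:
        return set(self.mapping.values())

    def validate_against(self, model: NetworkModel) -> None:
        missing = sorted(n for n in self.nodes() if not model.has_node(n))
        if missing:
            raise UnknownNodeError(f"gene-node map targets unknown nodes: {missing}")


def _read_data(filename: str) -> str:
    return resources.files("braflogic.data").joinpath(filename).read_text("utf-8")


def load_default_annotations() -> FunctionalAnnotation:
    """Packaged OncoKB-style functional annotation table."""
    return FunctionalAnnotation.from_tsv(_read_data("functional_annotations.tsv"))


def load_default_gene_node_map() -> GeneNodeMap:
    """Packaged gene symbol -> model node mapping for the BRAF network."""
    return GeneNodeMap.from_tsv(_read_data("gene_node_map.tsv"))


@dataclass
class CellLineProfile:
    """Interpreted omics profile of one cell line on the model's node space."""

    id: str
    tissue: str = "other"  # melanoma | CRC | other
    effects: dict[str, str] = field(default_factory=dict)  # node -> GOF/LOF
    expression: dict[str, float] = field(default_factory=dict)  # node -> x in [0,1]

    def __post_init__(self) -> None:
        for node, x in self.expression.items():
            if not (0.0 <= x <= 1.0):
                raise ModelValidationError(
                    f"{self.id}: expression value for {node} outside [0,1]: {x}"
                )
        for node, effect in self.effects.items():
            if effect not in (GOF, LOF):
                raise ValueError(f"{self.id}: invalid effect {effect!r} for {node}")


@dataclass
class PersonalizedModel:
    """A cell-line-specific model with provenance of every override."""

    model: NetworkModel
    initial_condition: InitialCondition
    strategy: str
    cell_line: str = ""
    forced_nodes: dict[str, tuple[int, str]] = field(default_factory=dict)  # node -> (level, effect)
    rate_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_overrides: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Discrete strategy
# ---------------------------------------------------------------------------


def interpret_mutations(
    records: list[MutationRecord],
    annotations: FunctionalAnnotation,
    gene_map: GeneNodeMap,
) -> dict[str, dict[str, str]]:
    """Turn mutation calls into per-cell-line node effects.

    Unannotated mutations and genes absent from the map are dropped.  A GOF
    and a LOF landing on the same node in one cell line is an error.
    """
    out: dict[str, dict[str, str]] = {}
    for rec in records:
        effect = annotations.effect_of(rec.gene, rec.protein_change)
        if effect is None:
            continue
        node = gene_map.node_for(rec.gene)
        if node is None:
            continue
        effects = out.setdefault(rec.cell_line, {})
        prev = effects.get(node)
        if prev is not None and prev != effect:
            raise ModelValidationError(
                f"{rec.cell_line}: conflicting effects on node {node} "
                f"({prev} vs {effect} from {rec.gene} {rec.protein_change})"
            )
        effects[node] = effect
    return out


def personalize_discrete(
    model: NetworkModel, profile: CellLineProfile
) -> PersonalizedModel:
    """Force GOF nodes to their maximum level and LOF nodes to 0."""
    perturbation: dict[str, int] = {}
    forced: dict[str, tuple[int, str]] = {}
    for node, effect in profile.effects.items():
        spec = model.node(node)
        level = spec.max_level if effect == GOF else 0
        perturbation[node] = level
        forced[node] = (level, effect)
    return PersonalizedModel(
        model=apply_perturbations(model, perturbation),
        initial_condition=InitialCondition(),
        strategy="mutations",
        cell_line=profile.id,
        forced_nodes=forced,
    )


# ---------------------------------------------------------------------------
# Continuous strategy
# ---------------------------------------------------------------------------


def normalize_expression(
    matrix: pd.DataFrame,
    method: str = "minmax",
    clip_percentiles: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Gene-wise min-max normalization of a genes x samples matrix to [0,1].

    Constant genes map to 0.5.  With ``clip_percentiles = (lo, hi)`` the
    per-gene range is first winsorized to those percentiles, making the
    scaling robust to outliers.
    """
    if method != "minmax":
        raise ValueError(f"unknown normalization method: {method!r}")
    if matrix.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    if (matrix.values < 0).any():
        raise ModelValidationError("expression matrix contains negative values")
    values = matrix.to_numpy(dtype=float)
    if clip_percentiles is not None:
        lo, hi = clip_percentiles
        low = np.percentile(values, lo, axis=1, keepdims=True)
        high = np.percentile(values, hi, axis=1, keepdims=True)
        values = np.clip(values, low, high)
    vmin = values.min(axis=1, keepdims=True)
    vmax = values.max(axis=1, keepdims=True)
    span = vmax - vmin
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = (values - vmin) / span
    norm[np.repeat(span == 0, values.shape[1], axis=1)] = 0.5
    return pd.DataFrame(norm, index=matrix.index, columns=matrix.columns)


def expression_to_node_values(
    normalized: pd.DataFrame, gene_map: GeneNodeMap, cell_line: str
) -> dict[str, float]:
    """Project a cell line's normalized expression onto model nodes.

    Family nodes fed by several paralogs (e.g. RAS from NRAS/KRAS/HRAS)
    average across paralogs: node activity potential reflects total isoform
    dosage.
    """
    if cell_line not in normalized.columns:
        raise KeyError(f"cell line {cell_line!r} not in expression matrix")
    column = normalized[cell_line]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for gene, x in column.items():
        if str(gene) not in gene_map.rna_genes:
            continue
        node = gene_map.node_for(str(gene))
        if node is None:
            continue
        sums[node] = sums.get(node, 0.0) + float(x)
        counts[node] = counts.get(node, 0) + 1
    return {node: sums[node] / counts[node] for node in sums}


def rate_from_value(x: float, amplification: float = 100.0) -> tuple[float, float]:
    """Map a normalized activity proxy to (rate_up, rate_down).

    ``rate_up = A^(2x-1)`` and ``rate_down = A^(1-2x)``: the midpoint 0.5 is
    exactly neutral (1, 1), extremes skew the rates by the amplification
    factor in opposite directions, and the product is always 1.
    """
    if not (0.0 <= x <= 1.0):
        raise ModelValidationError(f"expression value outside [0,1]: {x}")
    if not amplification > 1.0:
        raise ModelValidationError("amplification must be > 1")
    up = float(amplification ** (2.0 * x - 1.0))
    return up, 1.0 / up


def personalize_continuous(
    model: NetworkModel,
    profile: CellLineProfile,
    amplification: float = 100.0,
) -> PersonalizedModel:
    """Set initial activation and transition rates from normalized expression.

    Mapped nodes get initial activation ``a = x`` and rates from
    :func:`rate_from_value`; unmapped nodes keep their defaults (initial
    0.5, rates 1).
    """
    out = model.copy()
    rate_overrides: dict[str, tuple[float, float]] = {}
    for node, x in profile.expression.items():
        idx = out.node_index(node)
        spec = out.nodes[idx]
        up, down = rate_from_value(x, amplification)
        out.nodes[idx] = NodeSpec(
            name=spec.name,
            max_level=spec.max_level,
            is_input=spec.is_input,
            rate_up=up,
            rate_down=down,
        )
        rate_overrides[node] = (up, down)
    return PersonalizedModel(
        model=out,
        initial_condition=InitialCondition(dict(profile.expression)),
        strategy="rna",
        cell_line=profile.id,
        rate_overrides=rate_overrides,
        initial_overrides=dict(profile.expression),
    )


def personalize(
    model: NetworkModel,
    profile: CellLineProfile,
    strategy: str,
    amplification: float = 100.0,
) -> PersonalizedModel:
    """Personalize with one of the strategies ``mutations``/``rna``/``mutations+rna``.

    In the combined strategy mutation forcing dominates: forced nodes lose
    their rate and initial-condition overrides.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if strategy == "mutations":
        return personalize_discrete(model, profile)
    continuous = personalize_continuous(model, profile, amplification)
    if strategy == "rna":
        return continuous
    discrete = personalize_discrete(continuous.model, profile)
    # mutation dominates: strip rate/initial overrides on forced nodes
    merged_model = discrete.model
    rate_overrides = dict(continuous.rate_overrides)
    initial_overrides = dict(continuous.initial_overrides)
    for node in discrete.forced_nodes:
        if node in rate_overrides:
            idx = merged_model.node_index(node)
            spec = merged_model.nodes[idx]
            merged_model.nodes[idx] = NodeSpec(
                name=spec.name,
                max_level=spec.max_level,
                is_input=spec.is_input,
                rate_up=1.0,
                rate_down=1.0,
            )
            del rate_overrides[node]
        initial_overrides.pop(node, None)
    ic = InitialCondition(
        {n: a for n, a in continuous.initial_condition.items() if n in initial_overrides}
    )
    return PersonalizedModel(
        model=merged_model,
        initial_condition=ic,
        strategy="mutations+rna",
        cell_line=profile.id,
        forced_nodes=dict(discrete.forced_nodes),
        rate_overrides=rate_overrides,
        initial_overrides=initial_overrides,
    )
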