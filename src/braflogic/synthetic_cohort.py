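"""Synthetic melanoma / colorectal cell-line cohorts.

No real screening data ship with the package; this module generates cohorts
with the statistical structure the validation pipeline assumes, emulating
Cell Model Passports / GDSC-shaped exports:

* tissue-specific mutation frequencies for BRAF, the RAS family
  (NRAS in melanoma, KRAS in colorectal), TP53, PTEN and PIK3CA, with
  hotspot protein changes matching the packaged functional annotations;
* tissue-shifted expression (SOX10 high in melanoma, EGFR high in
  colorectal, CRAF/RAF1 and PDPK1 heterogeneous across both);
* a mechanistic latent sensitivity ``s`` per cell line that rises with
  BRAF gain-of-function and falls with RAS activation, high CRAF, high
  PDPK1 and PTEN-loss/PI3K-activation — the narrated resistance logic of
  the biological system — from which drug AUC (anti-correlated with ``s``)
  and CRISPR scaled Bayes factors (correlated with ``s``) are derived.

Everything is reproducible from the config seed, and read/write round-trips
through plain TSV files shaped like the personalization module's readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_sensitivities",
    "write_cohort",
    "read_cohort",
]

MELANOMA = "melanoma"
CRC = "CRC"

# hotspot protein changes consistent with the packaged annotation table
_HOTSPOTS = {
    "BRAF": "V600E",
    "NRAS": "Q61K",
    "KRAS": "G12D",
    "TP53": "R213*",
    "PTEN": "R130fs",
    "PIK3CA": "E545K",
}

_DEFAULT_MUTATION_FREQUENCIES: dict[tuple[str, str], float] = {
    (MELANOMA, "BRAF"): 0.50,
    (CRC, "BRAF"): 0.15,
    (MELANOMA, "RAS"): 0.25,
    (CRC, "RAS"): 0.40,
    (MELANOMA, "TP53"): 0.20,
    (CRC, "TP53"): 0.60,
    (MELANOMA, "PTEN"): 0.15,
    (CRC, "PTEN"): 0.10,
    (MELANOMA, "PIK3CA"): 0.05,
    (CRC, "PIK3CA"): 0.20,
}

# per-gene expression generators: (melanoma mean, CRC mean, sd)
_DEFAULT_EXPRESSION: dict[str, tuple[float, float, float]] = {
    "SOX10": (8.0, 2.0, 1.0),
    "FOXD3": (6.0, 4.0, 1.0),
    "EGFR": (3.0, 7.0, 1.0),
    "ERBB2": (4.5, 5.5, 1.0),
    "ERBB3": (5.0, 5.0, 1.0),
    "MET": (4.5, 5.5, 1.0),
    "FGFR2": (4.5, 5.5, 1.0),
    "NRG1": (5.5, 4.5, 1.0),
    "EGF": (5.0, 5.0, 1.0),
    "HGF": (5.0, 5.0, 1.0),
    "FGF2": (5.0, 5.0, 1.0),
    "ATM": (5.0, 5.0, 1.0),
    "GRB2": (5.0, 5.0, 1.0),
    "SOS1": (5.0, 5.0, 1.0),
    "GAB1": (5.0, 5.0, 1.0),
    "SPRY2": (5.5, 4.5, 1.0),
    "NRAS": (5.0, 5.0, 1.0),
    "KRAS": (5.0, 5.0, 1.0),
    "HRAS": (5.0, 5.0, 1.0),
    "BRAF": (5.0, 5.0, 1.0),
    "RAF1": (5.0, 5.0, 0.8),  # heterogeneous (bimodal, see below): drives differential resistance
    "MAP2K1": (5.0, 5.0, 1.0),
    "MAPK1": (5.0, 5.0, 1.0),
    "PIK3CA": (5.0, 5.0, 1.0),
    "PTEN": (4.5, 5.5, 1.0),
    "PDPK1": (5.0, 5.0, 0.8),  # heterogeneous (bimodal, see below)
    "AKT1": (5.5, 4.5, 1.0),
    "MTOR": (5.0, 5.0, 1.0),
    "RPS6KB1": (5.0, 5.0, 1.0),
    "TP53": (5.0, 5.0, 1.0),
    "CDKN1A": (5.5, 4.5, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, mutation frequencies, expression shifts and noise scales."""

    n_melanoma: int = 60
    n_crc: int = 60
    mutation_frequencies: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_MUTATION_FREQUENCIES)
    )
    expression_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_EXPRESSION)
    )
    # genes drawn from a symmetric two-mode mixture (baseline +- delta),
    # emulating the distinctly-low vs distinctly-high subgroups (e.g. CRAF in
    # SK-MEL-24/HT-29-like vs HT-144-like lines) that drive differential
    # resistance in the emulated system
    bimodal_genes: dict[str, float] = field(
        default_factory=lambda: {"RAF1": 2.0, "PDPK1": 2.0}
    )
    outlier_fraction: float = 0.03  # probability a background-gene value is an outlier
    outlier_scale: float = 5.0  # outlier sd as a multiple of the gene's sd
    sensitivity_noise: float = 0.05  # sd of the latent-sensitivity noise
    auc_noise: float = 0.04  # sd of the AUC measurement noise
    bf_noise: float = 0.40  # sd of the Bayes-factor measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_melanoma < 1 or self.n_crc < 1:
            raise ValueError("cohort sizes must be >= 1")
        for key, freq in self.mutation_frequencies.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(f"mutation frequency for {key} outside [0,1]: {freq}")


@dataclass
class Cohort:
    """A generated cohort: sample sheet, omics tables and latent ground truth."""

    samples: pd.DataFrame  # columns: cell_line, tissue
    mutations: pd.DataFrame  # columns: cell_line, gene, protein_change
    expression: pd.DataFrame  # genes x cell lines, raw non-negative values
    truth: pd.DataFrame  # columns: cell_line, s (latent sensitivity in [0,1])

    @property
    def cell_lines(self) -> list[str]:
        return list(self.samples["cell_line"])


def _minmax(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort of melanoma and colorectal cell lines.

    Mutations are independent Bernoulli draws at the configured
    (tissue, gene) frequencies; the RAS family uses NRAS in melanoma and
    KRAS in colorectal lines.  Expression is Gaussian around tissue-specific
    means, truncated at 0.  The latent sensitivity combines the generated
    features:

    ``s = clip(0.15 + 0.55 BRAF_GOF - 0.25 RAS_GOF - 0.25 craf - 0.15 pdpk1
    - 0.25 (PTEN_LOF or PIK3CA_GOF) + noise, 0, 1)``

    with ``craf``/``pdpk1`` the cohort-min-max-normalized RAF1/PDPK1
    expression of the line.
    """
    rng = np.random.default_rng(config.seed)
    tissues = [MELANOMA] * config.n_melanoma + [CRC] * config.n_crc
    ids = [
        f"MEL-{i + 1:03d}" for i in range(config.n_melanoma)
    ] + [f"CRC-{i + 1:03d}" for i in range(config.n_crc)]
    samples = pd.DataFrame({"cell_line": ids, "tissue": tissues})

    mut_rows: list[tuple[str, str, str]] = []
    flags = {gene: np.zeros(len(ids), dtype=bool) for gene in ("BRAF", "RAS", "TP53", "PTEN", "PIK3CA")}
    for i, (cid, tissue) in enumerate(zip(ids, tissues)):
        for gene in ("BRAF", "RAS", "TP53", "PTEN", "PIK3CA"):
            freq = config.mutation_frequencies.get((tissue, gene), 0.0)
            if gene == "RAS" and flags["BRAF"][i]:
                # BRAF V600 and RAS hotspot mutations are mutually exclusive
                continue
            if rng.random() < freq:
                flags[gene][i] = True
                symbol = gene
                if gene == "RAS":
                    symbol = "NRAS" if tissue == MELANOMA else "KRAS"
                mut_rows.append((cid, symbol, _HOTSPOTS[symbol]))
    mutations = pd.DataFrame(mut_rows, columns=["cell_line", "gene", "protein_change"])

    genes = sorted(config.expression_params)
    values = np.empty((len(genes), len(ids)))
    tissue_idx = np.array([t == MELANOMA for t in tissues])
    for g, gene in enumerate(genes):
        mel_mean, crc_mean, sd = config.expression_params[gene]
        mean = np.where(tissue_idx, mel_mean, crc_mean)
        delta = config.bimodal_genes.get(gene, 0.0)
        if delta:
            # the low/high heterogeneity of these genes is the structure of
            # interest; keep their within-mode noise Gaussian
            mean = mean + np.where(rng.random(len(ids)) < 0.5, -delta, delta)
            noise = rng.normal(0.0, sd, size=len(ids))
        else:
            # background genes carry occasional outlier lines (amplified or
            # silenced), which dominate per-gene ranges the way they do in
            # real expression matrices
            noise = rng.normal(0.0, sd, size=len(ids))
            outliers = rng.random(len(ids)) < config.outlier_fraction
            noise = np.where(
                outliers, rng.normal(0.0, config.outlier_scale * sd, size=len(ids)), noise
            )
        values[g] = np.clip(mean + noise, 0.0, None)
    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=ids)

    craf = _minmax(expression.loc["RAF1"].to_numpy())
    pdpk1 = _minmax(expression.loc["PDPK1"].to_numpy())
    s = (
        0.15
        + 0.55 * flags["BRAF"]
        - 0.25 * flags["RAS"]
        - 0.25 * craf
        - 0.15 * pdpk1
        - 0.25 * (flags["PTEN"] | flags["PIK3CA"])
        + rng.normal(0.0, config.sensitivity_noise, size=len(ids))
    )
    truth = pd.DataFrame({"cell_line": ids, "s": np.clip(s, 0.0, 1.0)})
    return Cohort(samples=samples, mutations=mutations, expression=expression, truth=truth)


def generate_sensitivities(cohort: Cohort, config: CohortConfig) -> pd.DataFrame:
    """Derive drug-AUC and CRISPR Bayes-factor tables from the latent truth.

    ``AUC = clip(1 - 0.5 s + noise, 0, 1)`` (lower = more sensitive) and
    ``scaled Bayes factor = 8 s - 2 + noise`` (higher = more essential), so
    the two metrics are anti-correlated by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])
    s = cohort.truth["s"].to_numpy()
    ids = cohort.truth["cell_line"]
    auc = np.clip(1.0 - 0.5 * s + rng.normal(0.0, config.auc_noise, len(s)), 0.0, 1.0)
    bf = 8.0 * s - 2.0 + rng.normal(0.0, config.bf_noise, len(s))
    return pd.DataFrame(
        {
            "cell_line": list(ids) * 2,
            "target": ["BRAF"] * (2 * len(s)),
            "metric": ["auc"] * len(s) + ["scaled_bayes_factor"] * len(s),
            "value": np.concatenate([auc, bf]),
        }
    )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------


def write_cohort(
    cohort: Cohort, directory: str | Path, sensitivities: pd.DataFrame | None = None
) -> dict[str, Path]:
    """Write the cohort as TSV files; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / "samples.tsv",
        "mutations": directory / "mutations.tsv",
        "expression": directory / "expression.tsv",
        "truth": directory / "ground_truth.tsv",
    }
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if sensitivities is not None:
        paths["sensitivities"] = directory / "sensitivities.tsv"
        sensitivities.to_csv(paths["sensitivities"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | Path) -> tuple[Cohort, pd.DataFrame | None]:
    """Read a cohort back from :func:`write_cohort` output, with validation."""
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    if not {"cell_line", "tissue"}.issubset(samples.columns):
        raise ValueError("samples.tsv needs columns cell_line, tissue")
    dup = samples["cell_line"][samples["cell_line"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell-line ids: {sorted(set(dup))}")
    mutations = pd.read_csv(directory / "mutations.tsv", sep="\t")
    if len(mutations) and not {"cell_line", "gene", "protein_change"}.issubset(
        mutations.columns
    ):
        raise ValueError("mutations.tsv needs columns cell_line, gene, protein_change")
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col="gene")
    if (expression.values < 0).any():
        raise ValueError("expression.tsv contains negative values")
    missing = sorted(set(samples["cell_line"]) - set(expression.columns))
    if missing:
        raise ValueError(f"expression.tsv missing columns for cell lines: {missing}")
    truth_path = directory / "ground_truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t")
        if truth_path.exists()
        else pd.DataFrame(columns=["cell_line", "s"])
    )
    sens_path = directory / "sensitivities.tsv"
    sensitivities = pd.read_csv(sens_path, sep="\t") if sens_path.exists() else None
    cohort = Cohort(
        samples=samples, mutations=mutations, expression=expression, truth=truth
    )
    return cohort, sensitivities
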