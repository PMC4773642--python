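"""Synthetic study generator with known planted truth.

Emulates the study design the pipeline expects: 9 sample groups (4 varieties,
5 extreme-phenotype seedling pools) x 3 biological replicates over ~37k array
features.  Expression is modelled on the log2 scale as

    log2 value = gene baseline + group effect + replicate noise

with the baseline drawn once per gene and shared across groups (preserving the
gene-wise pairing of real arrays), i.i.d. Gaussian replicate noise, and linear
values 2**(.).  Planted trait effects follow the three-way concordance logic:
a *concordant* gene carries the same signed log2 shift in the trait's
Chiquitita-like pool and in the Chiquitita reference itself, so the primary
contrast separates while the concordance contrast stays null; a *discordant*
gene carries the opposite shift in the reference, so the concordance contrast
fires and the three-way filter should reject it.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, StudyDesign, default_design

__all__ = [
    "PlantedTrait",
    "SimulationParams",
    "PlantedGene",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_ct_table",
    "truth_frame",
]

#: groups sharing the planted effect (concordant case), per trait of the
#: default design: the trait's "reference-phenotype" pool plus Chiquitita
#: (for growth habit: Chiquitita plus its like-canopy pool).
_EFFECT_GROUPS = {
    "internode_length": ("SILe", "Chiquitita"),
    "trunk_diameter": ("SmaD", "Chiquitita"),
    "growth_habit": ("Chiquitita", "ChiCa"),
}
#: the reference-variety member of the effect pair, flipped for discordant genes
_REFERENCE_GROUP = {
    "internode_length": "Chiquitita",
    "trunk_diameter": "Chiquitita",
    "growth_habit": "ChiCa",
}


@dataclass(frozen=True)
class PlantedTrait:
    """Planted signal for one trait: counts and the log2 effect magnitude."""

    trait: str
    n_concordant: int = 50
    n_discordant: int = 0
    log2_effect: float = 1.5


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int = 5000
    n_replicates: int = 3
    design: StudyDesign = field(default_factory=default_design)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    replicate_sd: float = 0.2
    planted: tuple[PlantedTrait, ...] = (
        PlantedTrait("internode_length"),
        PlantedTrait("trunk_diameter"),
        PlantedTrait("growth_habit"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be > 0")
        if self.baseline_log2_sd < 0:
            raise ValueError("baseline_log2_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        total = sum(p.n_concordant + p.n_discordant for p in self.planted)
        if total > self.n_genes:
            raise ValueError(
                f"{total} planted genes requested but only {self.n_genes} genes"
            )
        for p in self.planted:
            if p.trait not in _EFFECT_GROUPS:
                raise ValueError(f"no planted-effect rule for trait {p.trait!r}")

    def null(self) -> "SimulationParams":
        """Copy with all planted effects removed."""
        return replace(self, planted=())


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    trait: str
    log2_effect: float  # signed, as applied to the first primary-contrast group
    concordant: bool


def _gene_ids(n: int) -> tuple[str, ...]:
    return tuple(f"Contig_{i + 1}" for i in range(n))


def simulate_expression(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, list[PlantedGene]]:
    """Generate a linear-scale expression matrix plus its planted truth.

    Planted gene sets are disjoint across traits, drawn without replacement
    from the gene universe.  Each planted gene's effect sign is random (+/-)
    with the stated magnitude.  Identical seed => identical matrix.
    """
    rng = np.random.default_rng(params.seed)
    gene_ids = _gene_ids(params.n_genes)
    groups = list(params.design.groups)
    g_index = {g: j for j, g in enumerate(groups)}

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, params.n_genes)
    effects = np.zeros((params.n_genes, len(groups)))

    n_planted_total = sum(p.n_concordant + p.n_discordant for p in params.planted)
    chosen = rng.choice(params.n_genes, size=n_planted_total, replace=False)
    truth: list[PlantedGene] = []
    cursor = 0
    for trait_spec in params.planted:
        eff_groups = _EFFECT_GROUPS[trait_spec.trait]
        ref_group = _REFERENCE_GROUP[trait_spec.trait]
        for concordant, count in (
            (True, trait_spec.n_concordant),
            (False, trait_spec.n_discordant),
        ):
            for i in chosen[cursor:cursor + count]:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                e = sign * trait_spec.log2_effect
                for g in eff_groups:
                    effects[i, g_index[g]] += e if (concordant or g != ref_group) else -e
                truth.append(PlantedGene(gene_ids[i], trait_spec.trait, e, concordant))
            cursor += count

    n_rep = params.n_replicates
    noise = rng.normal(0.0, params.replicate_sd, (params.n_genes, len(groups) * n_rep))
    log2_vals = (
        baseline[:, None]
        + np.repeat(effects, n_rep, axis=1)
        + noise
    )
    columns = tuple((g, k) for g in groups for k in range(1, n_rep + 1))
    matrix = ExpressionMatrix(gene_ids=gene_ids, columns=columns, values=2.0 ** log2_vals)
    return matrix, truth


def truth_frame(truth: list[PlantedGene]) -> pd.DataFrame:
    """Planted truth as a tidy frame (gene_id, trait, log2_effect, concordant)."""
    return pd.DataFrame(
        [(t.gene_id, t.trait, t.log2_effect, t.concordant) for t in truth],
        columns=["gene_id", "trait", "log2_effect", "concordant"],
    )


def simulate_phenotypes(
    n_seedlings: int = 120,
    diameter_mean: float = 75.0,
    diameter_sd: float = 20.0,
    internode_mean: float = 1.8,
    internode_sd: float = 0.5,
    branch_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-seedling diameter and five branch internode means for a cross.

    Defaults emulate the 120-seedling Picual x Arbequina progeny with trait
    spreads on the order of the published pool tables.  Each seedling draws a
    latent internode level; the five branch means scatter around it with
    ``branch_sd``.  Values are truncated away from zero (measurements are
    positive).  ``sd=0`` is rejected; pass a tiny sd for near-degenerate tests.
    """
    if diameter_sd < 0 or internode_sd < 0 or branch_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    diameter = np.maximum(rng.normal(diameter_mean, diameter_sd, n_seedlings), 1.0)
    latent = np.maximum(rng.normal(internode_mean, internode_sd, n_seedlings), 0.1)
    branches = np.maximum(
        latent[:, None] + rng.normal(0.0, branch_sd, (n_seedlings, 5)), 0.05
    )
    df = pd.DataFrame(
        {
            "seedling_id": [str(i + 1) for i in range(n_seedlings)],
            "mother": "Picual",
            "pollen_donor": "Arbequina",
            "diameter_mm": np.round(diameter, 2),
        }
    )
    for b in range(5):
        df[f"branch{b + 1}_mm"] = np.round(branches[:, b], 2)
    df["mean_internode_mm"] = df[[f"branch{b + 1}_mm" for b in range(5)]].mean(axis=1)
    return df


def simulate_ct_table(
    genes: dict[str, dict[str, float]],
    reference_ct: float = 18.0,
    ct_sd: float = 0.2,
    n_biological: int = 3,
    n_technical: int = 3,
    baseline_ct: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with technical-triplicate structure.

    ``genes`` maps gene -> {sample: log2 relative expression vs the first-listed
    sample}.  For each (sample, biological replicate, technical replicate) a
    target and a reference (actin) well are emitted.  The target Ct decreases
    one cycle per doubling of expression:

        Ct_target = baseline_ct - log2_rel + noise
        Ct_ref    = reference_ct + noise

    so the recovered relative expression ``2**-(Ct_t - Ct_r)`` equals
    ``2**(log2_rel + baseline offset)`` — ratios between samples recover the
    planted log2 differences exactly when ``ct_sd == 0``.
    """
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, sample_levels in genes.items():
        for sample, log2_rel in sample_levels.items():
            for bio in range(1, n_biological + 1):
                for tech in range(1, n_technical + 1):
                    ct_t = baseline_ct - log2_rel + (rng.normal(0, ct_sd) if ct_sd else 0.0)
                    ct_r = reference_ct + (rng.normal(0, ct_sd) if ct_sd else 0.0)
                    rows.append((sample, bio, gene, tech, ct_t, ct_r))
    return pd.DataFrame(
        rows,
        columns=["sample", "biological_rep", "gene", "tech_rep", "ct_target", "ct_reference"],
    )
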