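"""Shared settings for the analysis drivers: the reference study conditions
and the location of the simulated input bundle and result tables."""

from pathlib import Path

from olivearch.pipeline import simulate_bundle
from olivearch.synthetic_data import PlantedTrait, SimulationParams

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
BUNDLE_DIR = SCRATCH / "simulated_bundle"  # large generated inputs
PIPELINE_DIR = SCRATCH / "pipeline_run"    # full per-gene contrast tables
SEED = 1

#: reference study conditions: 5000 genes, 9 groups x 3 replicates, 50
#: concordant + 50 discordant planted genes per trait at |log2 effect| 1.5,
#: replicate noise sd 0.2 log2 units
STUDY_PARAMS = SimulationParams(
    n_genes=5000,
    replicate_sd=0.2,
    planted=tuple(
        PlantedTrait(t, n_concordant=50, n_discordant=50, log2_effect=1.5)
        for t in ("internode_length", "trunk_diameter", "growth_habit")
    ),
    seed=SEED,
)


def ensure_bundle() -> dict:
    """Simulate the input bundle if it is not on disk yet."""
    RESULTS.mkdir(exist_ok=True)
    expr = BUNDLE_DIR / "expression.tsv"
    if not expr.exists():
        return simulate_bundle(STUDY_PARAMS, BUNDLE_DIR)
    return {
        "expression": str(expr),
        "design": str(BUNDLE_DIR / "design.yaml"),
        "truth": str(BUNDLE_DIR / "truth.tsv"),
        "phenotypes": str(BUNDLE_DIR / "phenotypes.tsv"),
        "ct_table": str(BUNDLE_DIR / "ct_table.tsv"),
    }
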