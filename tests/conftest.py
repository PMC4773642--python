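import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from olivearch.io_formats import ExpressionMatrix, default_design
from olivearch.synthetic_data import PlantedTrait, SimulationParams, simulate_expression

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values_by_group: dict[str, np.ndarray], gene_ids=None) -> ExpressionMatrix:
    """Build a small linear-scale matrix from {group: (n_genes, n_reps) array}."""
    groups = list(values_by_group)
    n_genes = next(iter(values_by_group.values())).shape[0]
    gene_ids = gene_ids or tuple(f"Contig_{i+1}" for i in range(n_genes))
    columns = []
    blocks = []
    for g in groups:
        arr = np.asarray(values_by_group[g], dtype=float)
        blocks.append(arr)
        columns.extend((g, k) for k in range(1, arr.shape[1] + 1))
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        columns=tuple(columns),
        values=np.hstack(blocks),
    )


@pytest.fixture(scope="session")
def planted_study():
    """A 5000-gene study with 50 concordant + 50 discordant planted genes per
    trait at |log2 effect| 1.5 and replicate sd 0.2 — the reference study
    conditions for recovery checks."""
    params = SimulationParams(
        n_genes=5000,
        replicate_sd=0.2,
        planted=tuple(
            PlantedTrait(t, n_concordant=50, n_discordant=50, log2_effect=1.5)
            for t in ("internode_length", "trunk_diameter", "growth_habit")
        ),
        seed=20160302,
    )
    matrix, truth = simulate_expression(params)
    return params, matrix, truth


@pytest.fixture(scope="session")
def null_study():
    """A 5000-gene study with no planted effects."""
    params = SimulationParams(n_genes=5000, planted=(), seed=42)
    matrix, truth = simulate_expression(params)
    assert truth == []
    return params, matrix


@pytest.fixture(scope="session")
def design():
    return default_design()
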