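"""Candidate-set validation statistics: the random same-size gene-set
Kruskal-Wallis null and the Poisson overlap-significance test.

Kruskal-Wallis validation asks whether a candidate set's expression separates
the 9 sample groups more than chance sets of the same size do.  The
observation unit is the per-gene, per-group mean of log2 expression: genes are
the observations and the 9 groups the factor.  Random comparison sets are
drawn uniformly without replacement from the full gene universe, each exactly
the candidate size.

Overlap significance between two candidate sets of sizes nA and nB in a
universe of N genes models the chance overlap count as Poisson with rate
lambda = nA*nB/N and reports the exact upper tail P(X >= k) by direct series
summation (no normal approximation).  An exact hypergeometric tail is provided
as the reference model for cross-checking; the two agree closely whenever
nA, nB << N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "KWValidationReport",
    "OverlapReport",
    "kw_set_validation",
    "poisson_overlap_p",
    "hypergeometric_overlap_p",
]


@dataclass(frozen=True)
class KWValidationReport:
    set_size: int
    candidate_h: float
    candidate_p: float
    random_h: tuple[float, ...]
    random_p: tuple[float, ...]
    n_random: int
    seed: int
    alpha: float

    @property
    def median_random_p(self) -> float:
        return float(np.median(self.random_p))

    @property
    def fraction_random_significant(self) -> float:
        return float(np.mean(np.asarray(self.random_p) < self.alpha))

    def to_dict(self) -> dict:
        return {
            "set_size": self.set_size,
            "candidate_h": self.candidate_h,
            "candidate_p": self.candidate_p,
            "n_random": self.n_random,
            "median_random_p": self.median_random_p,
            "fraction_random_significant": self.fraction_random_significant,
            "seed": self.seed,
            "alpha": self.alpha,
        }


def _group_mean_log2(matrix: ExpressionMatrix) -> np.ndarray:
    """(n_genes, n_groups) per-group replicate-mean log2 expression."""
    cols = [np.log2(matrix.group_values(g)).mean(axis=1) for g in matrix.groups]
    return np.column_stack(cols)


def _kw(observations: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    samples = [observations[idx, j] for j in range(observations.shape[1])]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def kw_set_validation(
    matrix: ExpressionMatrix,
    gene_set: set[str] | frozenset[str] | list[str],
    n_random: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> KWValidationReport:
    """Kruskal-Wallis across the sample groups for a candidate set versus
    same-size random gene sets.

    Deterministic under ``seed``; ``n_random >= 1``; sets of fewer than two
    genes are rejected (no spread to rank).
    """
    gene_set = set(gene_set)
    if len(gene_set) < 2:
        raise ValueError("gene set must have >= 2 members")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    index = matrix.gene_index()
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")

    obs = _group_mean_log2(matrix)
    cand_idx = np.asarray(sorted(index[g] for g in gene_set))
    cand_h, cand_p = _kw(obs, cand_idx)

    rng = np.random.default_rng(seed)
    rand_h, rand_p = [], []
    for _ in range(n_random):
        ridx = rng.choice(matrix.n_genes, size=len(gene_set), replace=False)
        h, p = _kw(obs, ridx)
        rand_h.append(h)
        rand_p.append(p)

    return KWValidationReport(
        set_size=len(gene_set),
        candidate_h=cand_h,
        candidate_p=cand_p,
        random_h=tuple(rand_h),
        random_p=tuple(rand_p),
        n_random=n_random,
        seed=seed,
        alpha=alpha,
    )


@dataclass(frozen=True)
class OverlapReport:
    label: str
    n_a: int
    n_b: int
    universe: int
    k_observed: int
    expected: float  # lambda = nA*nB/N
    p_poisson: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "universe": self.universe,
            "k_observed": self.k_observed,
            "expected_overlap": self.expected,
            "p_poisson": self.p_poisson,
        }


def _poisson_upper_tail(lam: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(lam) by exact term summation.

    Sums the complementary lower tail term-by-term in float (terms are
    generated by the stable recurrence t_j = t_{j-1} * lam / j) and clips to
    [0, 1].
    """
    if k <= 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    terms = []
    t = math.exp(-lam)
    terms.append(t)
    for j in range(1, k):
        t *= lam / j
        terms.append(t)
    return float(min(1.0, max(0.0, 1.0 - math.fsum(terms))))


def poisson_overlap_p(
    n_a: int,
    n_b: int,
    universe: int,
    k_observed: int,
    label: str = "",
) -> OverlapReport:
    """Poisson model for the overlap of two gene sets in a shared universe.

    lambda = nA*nB/N is the expected overlap of independent uniform sets;
    the report carries the exact upper-tail p for the observed overlap.
    """
    if universe <= 0:
        raise ValueError("universe size must be > 0")
    if n_a < 0 or n_b < 0 or n_a > universe or n_b > universe:
        raise ValueError("set sizes must lie in [0, universe]")
    if k_observed < 0 or k_observed > min(n_a, n_b):
        raise ValueError("observed overlap must lie in [0, min(nA, nB)]")
    lam = n_a * n_b / universe
    return OverlapReport(
        label=label or f"{n_a}x{n_b}/{universe}",
        n_a=n_a,
        n_b=n_b,
        universe=universe,
        k_observed=k_observed,
        expected=lam,
        p_poisson=_poisson_upper_tail(lam, k_observed),
    )


def hypergeometric_overlap_p(n_a: int, n_b: int, universe: int, k: int) -> float:
    """Exact P(overlap >= k) for a uniform random nA-set against a fixed
    nB-set in a universe of N genes — the reference model for the Poisson
    approximation."""
    if universe <= 0:
        raise ValueError("universe size must be > 0")
    if n_a < 0 or n_b < 0 or n_a > universe or n_b > universe:
        raise ValueError("set sizes must lie in [0, universe]")
    if k < 0 or k > min(n_a, n_b):
        raise ValueError("observed overlap must lie in [0, min(nA, nB)]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, n_b, n_a))
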