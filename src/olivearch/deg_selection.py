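"""Differential-expression core: replicate QC, joint fold-change/t-test DEG
calling, three-way concordance filtering and Venn assembly.

A gene is a DEG for a contrast (A, B) when both hold:

* two-tailed equal-variance Student t-test p < alpha (df = n_a + n_b - 2), and
* fold change x̄/ȳ of the *linear* group means lies strictly outside
  [1/threshold, threshold] (default threshold 2 — "more than 2-fold", so a
  ratio of exactly 2 is not called).

The t-test runs on log2-transformed replicate values by default
(``test_scale="log2"``); intensities are variance-stabilized there, while the
fold change is always the ratio of linear means.  No gene-level multiple
testing correction is applied by default: the selection uses the raw per-gene
alpha, with Benjamini-Hochberg available as an opt-in.

The three-way rule then keeps the primary-contrast DEGs whose *concordance*
contrast (reference variety vs its like-phenotype pool) is NOT significant
(p >= alpha), i.e. genes tracking the phenotype rather than general pedigree
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CandidateSet, ExpressionMatrix

__all__ = [
    "ContrastResult",
    "VennSummary",
    "replicate_correlation",
    "two_group_contrast",
    "three_way_select",
    "venn_summary",
]


@dataclass(frozen=True)
class ContrastResult:
    group_a: str
    group_b: str
    alpha: float
    fc_threshold: float
    test_scale: str
    df: int
    table: pd.DataFrame  # index gene_id; mean_a mean_b fold_change log2_fc p_value is_deg

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def deg_ids(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_deg"]])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def replicate_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """All pairwise Pearson r between biological replicates, per group, on log2
    data.

    Returns a frame (group, rep_i, rep_j, pearson_r, defined); a zero-variance
    replicate column yields ``defined=False`` with r NaN.  High within-group r
    is the replicate-quality check applied before any contrast.
    """
    rows = []
    for group in matrix.groups:
        block = np.log2(np.maximum(matrix.group_values(group), np.finfo(float).tiny))
        reps = [k for g, k in matrix.columns if g == group]
        sds = block.std(axis=0)
        for i in range(block.shape[1]):
            for j in range(i + 1, block.shape[1]):
                if sds[i] == 0 or sds[j] == 0:
                    rows.append((group, reps[i], reps[j], np.nan, False))
                else:
                    r = float(np.corrcoef(block[:, i], block[:, j])[0, 1])
                    rows.append((group, reps[i], reps[j], r, True))
    return pd.DataFrame(rows, columns=["group", "rep_i", "rep_j", "pearson_r", "defined"])


def min_replicate_correlation(matrix: ExpressionMatrix) -> pd.Series:
    """Per-group minimum pairwise replicate correlation (QC summary)."""
    df = replicate_correlation(matrix)
    return df.groupby("group")["pearson_r"].min()


def two_group_contrast(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    test_scale: str = "log2",
    bh_correct: bool = False,
) -> ContrastResult:
    """Per-gene contrast of two sample groups with the joint FC + t-test rule.

    Degenerate genes (zero pooled variance) get p = 1 when the group means are
    equal and p = 0 (with a warning) when they differ.  ``bh_correct=True``
    replaces p-values by Benjamini-Hochberg adjusted ones before the DEG call.
    """
    if test_scale not in ("log2", "linear"):
        raise ValueError(f"test_scale must be 'log2' or 'linear', got {test_scale!r}")
    a_lin = matrix.group_values(group_a)
    b_lin = matrix.group_values(group_b)
    if np.any(a_lin <= 0) or np.any(b_lin <= 0):
        raise ValueError("non-positive linear expression values; cannot log-transform")

    a = np.log2(a_lin) if test_scale == "log2" else a_lin
    b = np.log2(b_lin) if test_scale == "log2" else b_lin
    n_a, n_b = a.shape[1], b.shape[1]
    dof = n_a + n_b - 2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 for constant genes
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(p, dtype=float)

    pooled_ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    degenerate = pooled_ss == 0
    if degenerate.any():
        eq = degenerate & np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & ~eq] = 0.0
        p[eq] = 1.0
        if (degenerate & ~eq).any():
            warnings.warn(
                f"{int((degenerate & ~eq).sum())} gene(s) with zero pooled variance "
                "and unequal means; p reported as 0",
                stacklevel=2,
            )

    if bh_correct:
        p = multipletests(p, method="fdr_bh")[1]

    mean_a = a_lin.mean(axis=1)
    mean_b = b_lin.mean(axis=1)
    fc = mean_a / mean_b
    is_deg = (p < alpha) & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold))

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": p,
            "is_deg": is_deg,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    return ContrastResult(
        group_a=group_a,
        group_b=group_b,
        alpha=alpha,
        fc_threshold=fc_threshold,
        test_scale=test_scale,
        df=dof,
        table=table,
    )


def three_way_select(
    primary: ContrastResult,
    concordance: ContrastResult,
    alpha: float | None = None,
    trait: str = "",
) -> CandidateSet:
    """Keep primary-contrast DEGs that are NOT significant in the concordance
    contrast (p >= alpha); direction is the sign of the primary log2 fold
    change ('over' = higher in the first primary group)."""
    if not primary.gene_ids.equals(concordance.gene_ids):
        raise ValueError("primary and concordance contrasts cover different gene universes")
    if alpha is None:
        alpha = primary.alpha
    sel = primary.table["is_deg"] & (concordance.table["p_value"] >= alpha)
    sub = primary.table[sel]
    gene_ids = tuple(sub.index)
    return CandidateSet(
        trait=trait or f"{primary.group_a}_vs_{primary.group_b}",
        gene_ids=gene_ids,
        direction={g: ("over" if lfc > 0 else "under") for g, lfc in sub["log2_fc"].items()},
        fold_change=dict(sub["fold_change"]),
        p_value=dict(sub["p_value"]),
        provenance={
            "primary": f"{primary.group_a} vs {primary.group_b}",
            "concordance": f"{concordance.group_a} vs {concordance.group_b}",
            "alpha": str(alpha),
            "fc_threshold": str(primary.fc_threshold),
        },
    )


@dataclass(frozen=True)
class VennSummary:
    labels: tuple[str, str, str]
    sizes: tuple[int, int, int]
    pair_ab: int
    pair_ac: int
    pair_bc: int
    triple: int
    union_size: int
    union_members: frozenset[str]

    def __post_init__(self) -> None:
        incl_excl = (
            sum(self.sizes)
            - (self.pair_ab + self.pair_ac + self.pair_bc)
            + self.triple
        )
        if incl_excl != self.union_size:
            raise ValueError(
                f"inclusion-exclusion violated: {incl_excl} != {self.union_size}"
            )

    def to_dict(self) -> dict:
        a, b, c = self.labels
        return {
            "sizes": dict(zip(self.labels, self.sizes)),
            "pairwise": {f"{a}&{b}": self.pair_ab, f"{a}&{c}": self.pair_ac, f"{b}&{c}": self.pair_bc},
            "triple": self.triple,
            "union": self.union_size,
        }


def venn_summary(sets: list[CandidateSet]) -> VennSummary:
    """Exact three-set algebra over candidate sets (sizes, overlaps, union)."""
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 candidate sets, got {len(sets)}")
    a, b, c = (s.as_set() for s in sets)
    return VennSummary(
        labels=tuple(s.trait for s in sets),
        sizes=(len(a), len(b), len(c)),
        pair_ab=len(a & b),
        pair_ac=len(a & c),
        pair_bc=len(b & c),
        triple=len(a & b & c),
        union_size=len(a | b | c),
        union_members=frozenset(a | b | c),
    )
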