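"""GO-term over/under-representation: two-tailed Fisher's exact test of a
candidate set against the array background, with Benjamini-Hochberg FDR.

For each term the 2x2 table is

    (in set, with term)   (in set, without term)
    (out of set, with)    (out of set, without)

and the two-sided p sums the hypergeometric probabilities of every table with
the same margins whose point probability does not exceed the observed one
(the standard Fisher convention, with a small relative tolerance on the
comparison).  Only terms directly assigned are tested unless an ontology edge
list is supplied, in which case annotations are first propagated to all
ancestors (true-path rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentRow",
    "fisher_two_tailed",
    "bh_fdr",
    "propagate_annotations",
    "enrich",
]

#: relative slack when comparing point probabilities in the two-sided sum
_REL_TOL = 1e-7


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int  # candidate genes carrying the term
    K: int  # candidate size
    n: int  # background genes carrying the term
    N: int  # background size
    p_two_tailed: float
    q: float
    direction: str  # over | under
    significant: bool


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Enumerates the full hypergeometric support for the fixed margins and sums
    probabilities <= the observed table's (within 1e-7 relative tolerance).
    All-zero margins return 1 by convention.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def propagate_annotations(
    annotations: Mapping[str, frozenset[str] | set[str]],
    edges: Iterable[tuple[str, str]],
) -> dict[str, frozenset[str]]:
    """Apply the true-path rule: each gene inherits all ancestors of its terms.

    ``edges`` are (child, parent) pairs of the ontology graph.
    """
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)

    ancestors_cache: dict[str, frozenset[str]] = {}

    def ancestors(term: str, seen: frozenset[str] = frozenset()) -> frozenset[str]:
        if term in ancestors_cache:
            return ancestors_cache[term]
        out: set[str] = set()
        for p in parents.get(term, ()):  # cycles tolerated via `seen`
            if p in seen:
                continue
            out.add(p)
            out |= ancestors(p, seen | {term})
        result = frozenset(out)
        ancestors_cache[term] = result
        return result

    return {
        g: frozenset(set(terms) | set().union(*(ancestors(t) for t in terms)))
        for g, terms in annotations.items()
    }


def enrich(
    candidate: Iterable[str],
    annotations: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str],
    cutoff: float = 0.05,
    ontology_edges: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Term-wise two-tailed Fisher enrichment of a candidate set vs a background.

    ``background`` is the gene universe (the whole array, or its annotated
    part); the candidate must be a subset of it.  Returns a frame with one row
    per term present in the background, sorted by p then term id, with BH q
    computed over all tested terms and ``significant = q < cutoff``.
    """
    background_set = set(background)
    candidate_set = set(candidate)
    if not candidate_set <= background_set:
        extra = sorted(candidate_set - background_set)[:5]
        raise ValueError(f"candidate genes missing from background: {extra}")

    ann = {g: frozenset(ts) for g, ts in annotations.items() if g in background_set}
    if ontology_edges is not None:
        ann = propagate_annotations(ann, ontology_edges)

    term_to_genes: dict[str, set[str]] = {}
    for g, terms in ann.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(g)

    K = len(candidate_set)
    N = len(background_set)
    rows = []
    for term in sorted(term_to_genes):
        genes = term_to_genes[term]
        n = len(genes)
        k = len(genes & candidate_set)
        p = fisher_two_tailed([[k, K - k], [n - k, N - K - (n - k)]])
        direction = "over" if k * N > n * K else "under"
        rows.append((term, k, K, n, N, p, direction))

    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_two_tailed", "direction"])
    df["q"] = bh_fdr(df["p_two_tailed"]) if len(df) else []
    df["significant"] = df["q"] < cutoff
    df = df.sort_values(["p_two_tailed", "term"], kind="stable").reset_index(drop=True)
    return df[["term", "k", "K", "n", "N", "p_two_tailed", "q", "direction", "significant"]]
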