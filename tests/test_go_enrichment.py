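import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from olivearch.go_enrichment import bh_fdr, enrich, fisher_two_tailed, propagate_annotations

counts = st.integers(min_value=0, max_value=12)


def enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration over the support."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    probs = {k: math.comb(row1, k) * math.comb(n - row1, col1 - k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(v for v in probs.values() if v <= p_obs) / denom)


class TestFisherTwoTailed:
    def test_extreme_diagonal_table(self):
        # only the two perfectly separated tables are as extreme: 2/C(10,5)
        assert fisher_two_tailed([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    def test_proportional_table_p_one(self):
        assert fisher_two_tailed([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_all_zero_margins_convention(self):
        assert fisher_two_tailed([[0, 0], [0, 0]]) == 1.0

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed([[1, -1], [0, 0]])
        with pytest.raises(ValueError):
            fisher_two_tailed([[0.5, 1], [1, 1]])

    @given(counts, counts, counts, counts)
    def test_transposition_invariance(self, a, b, c, d):
        assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(
            fisher_two_tailed([[a, c], [b, d]]), rel=1e-9
        )

    @given(counts, counts, counts, counts)
    def test_matches_scipy_oracle(self, a, b, c, d):
        expected = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(expected, rel=1e-7)

    @given(counts, counts, counts, counts)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(
            enumeration_oracle(a, b, c, d), rel=1e-9
        )


class TestBhFdr:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.permutations(list(range(6))))
    def test_stable_under_permutation(self, perm):
        """Each p keeps its q regardless of input order."""
        base = [0.001, 0.02, 0.2, 0.4, 0.7, 0.9]
        q_base = dict(zip(base, bh_fdr(base)))
        shuffled = [base[i] for i in perm]
        for p, q in zip(shuffled, bh_fdr(shuffled)):
            assert q == pytest.approx(q_base[p])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def build_annotations(n_genes=500, n_terms=20, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"Contig_{i+1}" for i in range(n_genes)]
    ann = {}
    for g in genes:
        k = rng.integers(1, 4)
        ann[g] = frozenset(f"GO:{t:04d}" for t in rng.choice(n_terms, size=k, replace=False))
    return genes, ann


class TestEnrich:
    def test_extreme_enrichment_ranks_first(self):
        # candidate = exactly the 10 genes bearing GO:T; the rest split
        # between two other terms
        genes = [f"g{i}" for i in range(100)]
        ann = {g: frozenset({"GO:T"} if i < 10 else {"GO:o1"} if i < 55 else {"GO:o2"})
               for i, g in enumerate(genes)}
        table = enrich(genes[:10], ann, genes)
        top = table.iloc[0]
        assert top["term"] == "GO:T" and top["direction"] == "over"
        assert top["p_two_tailed"] == table["p_two_tailed"].min()

    def test_full_background_candidate_all_p_one(self):
        genes, ann = build_annotations(n_genes=60, seed=1)
        table = enrich(genes, ann, genes)
        assert np.allclose(table["p_two_tailed"], 1.0)

    def test_planted_term_flagged(self):
        """A 200-gene term contributing 40 of a 100-gene candidate in a
        5000-gene background is decisively over-represented."""
        genes = [f"g{i}" for i in range(5000)]
        ann = {g: frozenset({"GO:big"}) for g in genes[:200]}
        ann.update({g: frozenset({"GO:bg"}) for g in genes[200:]})
        candidate = genes[:40] + genes[200:260]
        table = enrich(candidate, ann, genes).set_index("term")
        row = table.loc["GO:big"]
        assert row["k"] == 40 and row["K"] == 100
        assert row["significant"] and row["direction"] == "over"
        # single hypergeometric tail confirms p is far below the cutoff
        assert stats.hypergeom.sf(39, 5000, 200, 100) < 1e-20

    def test_fdr_calibration_random_candidates(self):
        """Uniformly random candidate sets should almost never yield q < 0.05
        terms (FDR control across seeds)."""
        genes, ann = build_annotations(n_genes=400, n_terms=15, seed=2)
        rng = np.random.default_rng(7)
        flagged = 0
        total_terms = 0
        for _ in range(40):
            candidate = list(rng.choice(genes, size=50, replace=False))
            table = enrich(candidate, ann, genes)
            flagged += int(table["significant"].sum())
            total_terms += len(table)
        assert flagged / total_terms < 0.02

    def test_flagged_at_q_subset_of_flagged_at_p(self):
        genes, ann = build_annotations(n_genes=300, seed=3)
        rng = np.random.default_rng(11)
        candidate = list(rng.choice(genes, size=60, replace=False))
        table = enrich(candidate, ann, genes)
        if (table["q"] >= table["p_two_tailed"]).all():
            q_flag = set(table.loc[table["q"] < 0.05, "term"])
            p_flag = set(table.loc[table["p_two_tailed"] < 0.05, "term"])
            assert q_flag <= p_flag

    def test_candidate_outside_background_rejected(self):
        genes, ann = build_annotations(n_genes=20, seed=4)
        with pytest.raises(ValueError, match="missing from background"):
            enrich(["nope"], ann, genes)

    def test_ontology_propagation(self):
        ann = {"g1": {"GO:leaf"}, "g2": {"GO:mid"}, "g3": {"GO:root"}}
        edges = [("GO:leaf", "GO:mid"), ("GO:mid", "GO:root")]
        propagated = propagate_annotations(ann, edges)
        assert propagated["g1"] == frozenset({"GO:leaf", "GO:mid", "GO:root"})
        assert propagated["g2"] == frozenset({"GO:mid", "GO:root"})
        table = enrich(["g1"], ann, ["g1", "g2", "g3"], ontology_edges=edges)
        root = table.set_index("term").loc["GO:root"]
        assert root["n"] == 3 and root["k"] == 1
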