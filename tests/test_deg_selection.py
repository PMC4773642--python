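import numpy as np
import pytest
from scipy import stats

from olivearch.deg_selection import (
    replicate_correlation,
    three_way_select,
    two_group_contrast,
    venn_summary,
)
from olivearch.io_formats import CandidateSet
from olivearch.synthetic_data import SimulationParams, simulate_expression, truth_frame

from conftest import make_matrix


def two_group(a_rows, b_rows, **kw):
    a = np.asarray(a_rows, dtype=float)
    b = np.asarray(b_rows, dtype=float)
    return make_matrix({"A": a, "B": b})


class TestReplicateCorrelation:
    def test_identical_replicates_r_one(self):
        m = make_matrix({"A": np.tile([[1.0], [2.0], [8.0]], (1, 3))})
        rc = replicate_correlation(m)
        assert np.allclose(rc["pearson_r"], 1.0)

    def test_affine_transform_r_one(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        # affine on the log2 scale: log2(c * x**b) = log2 c + b*log2 x
        m = make_matrix({"A": np.column_stack([x, 3.0 * x**2])})
        rc = replicate_correlation(m)
        assert rc["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_column_flagged(self):
        m = make_matrix({"A": np.array([[1.0, 1.0], [1.0, 2.0]])})
        rc = replicate_correlation(m)
        assert not rc["defined"].iloc[0]
        assert np.isnan(rc["pearson_r"].iloc[0])

    def test_median_r_larger_at_lower_noise(self):
        """Monte-Carlo across seeds: tighter replicates correlate higher."""
        def med(sd, seed):
            m, _ = simulate_expression(
                SimulationParams(n_genes=100, replicate_sd=sd, planted=(), seed=seed)
            )
            return replicate_correlation(m)["pearson_r"].median()

        wins = sum(med(0.2, s) > med(1.0, s) for s in range(10))
        assert wins == 10


class TestTwoGroupContrast:
    def test_textbook_t_example(self):
        """(1,2,3) vs (4,5,6) on the tested scale: t=-3.674, df=4, p=0.0213."""
        m = two_group([[1, 2, 3]], [[4, 5, 6]])
        res = two_group_contrast(m, "A", "B", test_scale="linear")
        assert res.df == 4
        assert res.table["p_value"].iloc[0] == pytest.approx(0.02131, abs=1e-4)
        # cross-check against the independent implementation
        assert res.table["p_value"].iloc[0] == pytest.approx(
            stats.ttest_ind([1, 2, 3], [4, 5, 6]).pvalue, rel=1e-12
        )

    def test_identical_groups_not_deg(self):
        m = two_group([[5, 6, 7]], [[5, 6, 7]])
        res = two_group_contrast(m, "A", "B")
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)
        assert not res.table["is_deg"].iloc[0]

    def test_fold_change_exactly_two_not_deg(self):
        """'More than 2-fold' is strict: ratio exactly 2 fails even at p~0."""
        with pytest.warns(UserWarning, match="zero pooled variance"):
            m = two_group([[4, 4, 4]], [[2, 2, 2]])
            res = two_group_contrast(m, "A", "B")
        row = res.table.iloc[0]
        assert row["fold_change"] == pytest.approx(2.0)
        assert row["p_value"] == 0.0
        assert not row["is_deg"]

    def test_deg_rule_symmetric_under_group_swap(self, null_study):
        _, m = null_study
        ab = two_group_contrast(m, "SILe", "LILe")
        ba = two_group_contrast(m, "LILe", "SILe")
        assert (ab.table["is_deg"] == ba.table["is_deg"]).all()
        np.testing.assert_allclose(
            ab.table["fold_change"], 1.0 / ba.table["fold_change"], rtol=1e-12
        )
        np.testing.assert_allclose(ab.table["p_value"], ba.table["p_value"], rtol=1e-9)

    def test_nonpositive_values_rejected(self):
        m = make_matrix({"A": np.array([[0.0, 2.0]]), "B": np.array([[3.0, 4.0]])})
        with pytest.raises(ValueError, match="non-positive"):
            two_group_contrast(m, "A", "B")

    def test_brute_force_oracle_gene_for_gene(self):
        """Independent recomputation (means, pooled variance, t, p, rule) for a
        50-gene matrix matches the pipeline exactly."""
        rng = np.random.default_rng(12)
        a = 2.0 ** rng.normal(8, 1, (50, 3))
        b = 2.0 ** rng.normal(8, 1, (50, 4))
        m = make_matrix({"A": a, "B": b})
        res = two_group_contrast(m, "A", "B", alpha=0.05, fc_threshold=2.0)
        for i in range(50):
            x, y = np.log2(a[i]), np.log2(b[i])
            sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (len(x) + len(y) - 2)
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
            p = 2 * stats.t.sf(abs(t), len(x) + len(y) - 2)
            fc = a[i].mean() / b[i].mean()
            assert res.table["p_value"].iloc[i] == pytest.approx(p, rel=1e-9)
            assert res.table["fold_change"].iloc[i] == pytest.approx(fc, rel=1e-12)
            assert res.table["is_deg"].iloc[i] == ((p < 0.05) and (fc > 2 or fc < 0.5))

    def test_bh_switch_reduces_calls(self, null_study):
        _, m = null_study
        raw = two_group_contrast(m, "SILe", "LILe")
        adj = two_group_contrast(m, "SILe", "LILe", bh_correct=True)
        assert adj.table["is_deg"].sum() <= raw.table["is_deg"].sum()


class TestThreeWaySelect:
    def build(self, primary_p, primary_fc, concordance_p):
        """One-gene contrast pair with prescribed statistics."""
        lin_a = [4.0 * primary_fc, 4.0 * primary_fc * 1.01]
        lin_b = [4.0, 4.04]
        m = make_matrix({"A": np.array([lin_a]), "B": np.array([lin_b])})
        prim = two_group_contrast(m, "A", "B")
        prim.table["p_value"] = [primary_p]
        prim.table["is_deg"] = (prim.table["p_value"] < 0.05) & (
            (prim.table["fold_change"] > 2) | (prim.table["fold_change"] < 0.5)
        )
        conc = two_group_contrast(m, "A", "B")
        conc.table["p_value"] = [concordance_p]
        return prim, conc

    def test_rule_application(self):
        prim, conc = self.build(0.001, 3.0, 0.20)
        assert len(three_way_select(prim, conc, alpha=0.05)) == 1
        prim, conc = self.build(0.001, 3.0, 0.01)
        assert len(three_way_select(prim, conc, alpha=0.05)) == 0

    def test_output_subset_of_primary_degs(self, planted_study, design):
        _, m, _ = planted_study
        for d in design.three_way:
            prim = two_group_contrast(m, *d.primary)
            conc = two_group_contrast(m, *d.concordance)
            cs = three_way_select(prim, conc, trait=d.trait)
            assert cs.as_set() <= prim.deg_ids

    def test_concordant_vs_discordant_enrichment(self, planted_study, design):
        """With 50 concordant and 50 discordant planted genes per trait the
        selected set is enriched >= 9:1 for concordant ones."""
        _, m, truth = planted_study
        tf = truth_frame(truth)
        for d in design.three_way:
            prim = two_group_contrast(m, *d.primary)
            conc = two_group_contrast(m, *d.concordance)
            sel = three_way_select(prim, conc, trait=d.trait).as_set()
            sub = tf[tf["trait"] == d.trait]
            n_conc = len(sel & set(sub.loc[sub["concordant"], "gene_id"]))
            n_disc = len(sel & set(sub.loc[~sub["concordant"], "gene_id"]))
            assert n_conc >= 9 * max(n_disc, 1)

    def test_universe_mismatch_rejected(self):
        prim, _ = self.build(0.001, 3.0, 0.2)
        other = make_matrix({"A": np.ones((2, 2)), "B": np.ones((2, 2)) * 2})
        conc = two_group_contrast(other, "A", "B")
        with pytest.raises(ValueError, match="universe"):
            three_way_select(prim, conc)

    def test_direction_follows_primary_sign(self):
        m = make_matrix({"A": np.array([[8.0, 8.2], [1.0, 1.05]]),
                         "B": np.array([[1.0, 1.05], [8.0, 8.2]])})
        prim = two_group_contrast(m, "A", "B")
        conc_m = make_matrix({"A": np.array([[1.0, 1.3], [1.0, 1.3]]),
                              "B": np.array([[1.1, 1.2], [1.1, 1.2]])})
        conc = two_group_contrast(conc_m, "A", "B")
        cs = three_way_select(prim, conc)
        assert cs.direction == {"Contig_1": "over", "Contig_2": "under"}


class TestVennSummary:
    @staticmethod
    def cs(trait, genes):
        return CandidateSet(trait=trait, gene_ids=tuple(genes),
                            direction={g: "over" for g in genes})

    def test_disjoint_sets_sum(self):
        sets = [self.cs("a", ["g1"]), self.cs("b", ["g2", "g3"]), self.cs("c", ["g4"])]
        assert venn_summary(sets).union_size == 4

    def test_identical_sets(self):
        genes = ["g1", "g2"]
        sets = [self.cs(t, genes) for t in "abc"]
        vs = venn_summary(sets)
        assert vs.union_size == 2 and vs.triple == 2

    def test_brute_force_oracle_random_sets(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(60)]
        sets = [self.cs(t, rng.choice(universe, size=25, replace=False)) for t in "abc"]
        vs = venn_summary(sets)
        a, b, c = (set(s.gene_ids) for s in sets)
        assert vs.union_size == len(a | b | c)
        assert vs.pair_ab == len(a & b) and vs.triple == len(a & b & c)
        assert vs.union_members == frozenset(a | b | c)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            venn_summary([self.cs("a", ["g1"])])
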