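"""Tests of the differential-expression stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import regdiffnet as rd
from regdiffnet.de import (
    DEConfig,
    DEInputError,
    ExpressionMatrix,
    assign_clusters,
    build_deg_table,
    condition_means,
    contrast_name,
    default_contrasts,
)
from oracles import bh_stepup_bruteforce


def two_group(a_vals, b_vals, genes=("g",)):
    data = {}
    cond = {}
    for i, v in enumerate(a_vals):
        data[f"a{i}"] = v
        cond[f"a{i}"] = "A"
    for i, v in enumerate(b_vals):
        data[f"b{i}"] = v
        cond[f"b{i}"] = "B"
    values = pd.DataFrame(data, index=list(genes))
    return ExpressionMatrix(values, cond)


class TestOneWayAnova:
    def test_hand_computed_f(self):
        # groups {1,2,3} and {4,5,6}: SSB = 13.5, MSW = 1, df (1, 4)
        m = two_group([[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]])
        out = rd.one_way_anova(m)
        assert out["F"].iloc[0] == pytest.approx(13.5, abs=1e-12)
        assert out["anova_p"].iloc[0] == pytest.approx(
            sstats.f.sf(13.5, 1, 4), abs=1e-12
        )

    def test_constant_gene_flagged_with_p_one(self):
        m = two_group([[5.0]] * 4, [[5.0]] * 4)
        out = rd.one_way_anova(m)
        assert bool(out["anova_degenerate"].iloc[0])
        assert out["anova_p"].iloc[0] == 1.0

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(0)
        m = two_group(
            [list(rng.normal(size=10)) for _ in range(4)],
            [list(rng.normal(1, 1, size=10)) for _ in range(4)],
            genes=[f"g{i}" for i in range(10)],
        )
        f = rd.one_way_anova(m)["F"].to_numpy()
        t = rd.pairwise_t(m, (("A", "B"),))["t_A_vs_B"].to_numpy()
        np.testing.assert_allclose(f, t**2, atol=1e-10)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            rng.normal(size=(20, 9)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(9)],
        )
        cond = {f"s{i}": "ABC"[i // 3] for i in range(9)}
        m = ExpressionMatrix(vals, cond)
        out = rd.one_way_anova(m)
        for i in range(20):
            groups = [vals.iloc[i, 3 * k : 3 * k + 3] for k in range(3)]
            ref = sstats.f_oneway(*groups)
            assert out["F"].iloc[i] == pytest.approx(ref.statistic, rel=1e-10)
            assert out["anova_p"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_single_sample_condition_rejected(self):
        values = pd.DataFrame({"a0": [1.0], "a1": [2.0], "b0": [3.0]})
        m = ExpressionMatrix(values, {"a0": "A", "a1": "A", "b0": "B"})
        with pytest.raises(DEInputError):
            rd.one_way_anova(m)


class TestPairwiseT:
    def test_hand_computed_t(self):
        m = two_group([[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]])
        out = rd.pairwise_t(m, (("A", "B"),))
        assert out["log2fc_A_vs_B"].iloc[0] == pytest.approx(-3.0)
        assert out["t_A_vs_B"].iloc[0] == pytest.approx(-np.sqrt(13.5), abs=1e-12)
        assert out["p_A_vs_B"].iloc[0] == pytest.approx(0.0213, abs=5e-5)

    def test_constant_groups_give_fc_with_degenerate_flag(self):
        m = two_group([[2.0], [2.0]], [[1.0], [1.0]])
        out = rd.pairwise_t(m, (("A", "B"),))
        assert out["log2fc_A_vs_B"].iloc[0] == 1.0  # 2-fold on the log2 scale
        assert bool(out["degenerate_A_vs_B"].iloc[0])
        assert out["p_A_vs_B"].iloc[0] == 1.0

    def test_swapping_contrast_negates_fc_and_t(self):
        rng = np.random.default_rng(2)
        m = two_group(
            [list(rng.normal(size=8)) for _ in range(3)],
            [list(rng.normal(size=8)) for _ in range(3)],
            genes=["g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8"],
        )
        ab = rd.pairwise_t(m, (("A", "B"),))
        ba = rd.pairwise_t(m, (("B", "A"),))
        np.testing.assert_allclose(
            ab["log2fc_A_vs_B"], -ba["log2fc_B_vs_A"], atol=1e-14
        )
        np.testing.assert_allclose(ab["t_A_vs_B"], -ba["t_B_vs_A"], atol=1e-12)

    def test_cross_check_against_scipy_ttest(self):
        rng = np.random.default_rng(3)
        m = two_group(
            [list(rng.normal(size=6)) for _ in range(4)],
            [list(rng.normal(size=6)) for _ in range(5)],
            genes=[f"g{i}" for i in range(6)],
        )
        out = rd.pairwise_t(m, (("A", "B"),))
        a = m.condition_values("A")
        b = m.condition_values("B")
        ref = sstats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t_A_vs_B"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(out["p_A_vs_B"], ref.pvalue, rtol=1e-10)


class TestBHFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_cases(self, p, expected):
        np.testing.assert_allclose(rd.bh_fdr(p), expected, atol=1e-14)

    def test_rejects_out_of_range(self):
        with pytest.raises(DEInputError):
            rd.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_bruteforce_stepup_exactly(self, p):
        np.testing.assert_array_equal(rd.bh_fdr(p), bh_stepup_bruteforce(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(rd.bh_fdr(p), ref, atol=1e-12)


class TestFilterDegs:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["anova_q", "max_abs_log2fc"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_both_thresholds_must_hold(self):
        deg = self._table([(0.005, 1.2), (0.005, 0.5), (0.5, 3.0)])
        cfg = DEConfig()
        out = rd.filter_degs(deg, cfg)
        assert list(out.index) == ["g0"]

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(5)
        deg = self._table(
            [(rng.uniform(0, 0.05), rng.uniform(0, 2)) for _ in range(50)]
        )
        cfg = DEConfig(fold_change_threshold=2.0, q_threshold=0.01)
        out = rd.filter_degs(deg, cfg)
        expected = [
            g
            for g, row in deg.iterrows()
            if row["anova_q"] < 0.01 and row["max_abs_log2fc"] >= 1.0
        ]
        assert list(out.index) == expected

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(6)
        deg = self._table(
            [(rng.uniform(0, 0.05), rng.uniform(0, 2)) for _ in range(100)]
        )
        loose = set(rd.filter_degs(deg, DEConfig(2.0, 0.02)).index)
        tight_q = set(rd.filter_degs(deg, DEConfig(2.0, 0.005)).index)
        tight_fc = set(rd.filter_degs(deg, DEConfig(3.0, 0.02)).index)
        assert tight_q <= loose
        assert tight_fc <= loose


class TestAssignClusters:
    def _matrix(self, vals, conds=("A", "B", "C", "D")):
        data, cond = {}, {}
        for ci, c in enumerate(conds):
            for r in range(2):
                s = f"{c}{r}"
                data[s] = [row[ci] for row in vals]
                cond[s] = c
        return ExpressionMatrix(
            pd.DataFrame(data, index=[f"g{i}" for i in range(len(vals))]), cond
        )

    def test_orthogonal_patterns_form_singletons(self):
        m = self._matrix(
            [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0], [0, 0, 0, 10]]
        )
        out = assign_clusters(["g0", "g1", "g2", "g3"], m, 4)
        assert sorted(out["cluster"]) == [1, 2, 3, 4]

    def test_partition_invariant_to_gene_order(self):
        rng = np.random.default_rng(7)
        vals = [list(rng.normal(size=4)) for _ in range(12)]
        m = self._matrix(vals)
        genes = [f"g{i}" for i in range(12)]
        a = assign_clusters(genes, m, 3)
        b = assign_clusters(genes[::-1], m, 3)
        part_a = {frozenset(a.index[a["cluster"] == c]) for c in set(a["cluster"])}
        part_b = {frozenset(b.index[b["cluster"] == c]) for c in set(b["cluster"])}
        assert part_a == part_b

    def test_planted_regulon_shares_a_cluster_when_noiseless(self):
        cfg = rd.SyntheticConfig(
            n_tfs=4, n_genes=40, regulon_size=5, noise_sd=0.0,
            activity_cv=0.0, induced_activity_cv=0.0, seed=8,
        )
        prior = rd.generate_prior_truth(cfg)
        expr, truth = rd.generate_expression(prior, cfg)
        regulon = sorted(g for _, g in truth.differential_edges)
        others = [g for g in expr.values.index if g not in regulon][:10]
        out = assign_clusters(regulon + others, expr, 3)
        pure = {g for g in regulon if prior[g].sum() == 1}  # no overlapping TFs
        assert len(pure) >= 2
        assert len(set(out.loc[sorted(pure), "cluster"])) == 1

    def test_too_few_genes_rejected(self):
        m = self._matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        with pytest.raises(DEInputError):
            assign_clusters(["g0", "g1"], m, 4)


class TestZscoreRows:
    def test_hand_computed_row(self):
        z, flags, sat = rd.zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(
            z.iloc[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )
        assert not flags.iloc[0]

    def test_constant_row_zeroed_and_flagged(self):
        z, flags, _ = rd.zscore_rows(pd.DataFrame([[2.0, 2.0, 2.0]]))
        assert (z.iloc[0] == 0).all()
        assert bool(flags.iloc[0])

    def test_rows_have_zero_mean_unit_population_sd(self):
        rng = np.random.default_rng(9)
        z, flags, sat = rd.zscore_rows(
            pd.DataFrame(rng.normal(size=(30, 8)))
        )
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)
        assert sat.equals(z.abs() >= 2)


class TestPcaSamples:
    def _matrix(self, n_genes=30, seed=10):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.normal(size=(n_genes, 6)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(6)],
        )
        return ExpressionMatrix(vals, {f"s{i}": "AB"[i // 3] for i in range(6)})

    def test_duplicate_samples_coincide(self):
        m = self._matrix()
        vals = m.values.copy()
        vals["s5"] = vals["s0"]
        dup = ExpressionMatrix(vals, dict(m.condition_of))
        scores, _ = rd.pca_samples(dup)
        np.testing.assert_allclose(
            scores.loc["s0"], scores.loc["s5"], atol=1e-9
        )

    def test_explained_variance_sums_to_one(self):
        _, frac = rd.pca_samples(self._matrix())
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(frac.to_numpy()) <= 1e-12).all()

    def test_invariant_to_gene_permutation(self):
        m = self._matrix()
        perm = ExpressionMatrix(
            m.values.sample(frac=1, random_state=1), dict(m.condition_of)
        )
        a, _ = rd.pca_samples(m)
        b, _ = rd.pca_samples(perm)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_conditions_separate_on_pc1_for_planted_data(self):
        cfg = rd.SyntheticConfig(
            n_tfs=6, n_genes=60, regulon_size=6, noise_sd=0.0,
            activity_cv=0.0, induced_activity_cv=0.0, seed=12,
        )
        prior = rd.generate_prior_truth(cfg)
        expr, truth = rd.generate_expression(prior, cfg)
        scores, _ = rd.pca_samples(expr)
        by_cond = {
            c: scores.loc[expr.samples_of(c)].to_numpy() for c in cfg.conditions
        }
        # noiseless replicates coincide; the shifted condition stands apart
        for c, block in by_cond.items():
            np.testing.assert_allclose(
                block, np.broadcast_to(block[0], block.shape), atol=1e-9
            )
        shifted = truth.differential_condition
        ref = truth.reference_condition
        assert not np.allclose(
            by_cond[shifted][0, 0], by_cond[ref][0, 0], atol=1e-6
        )

    def test_cross_check_against_sklearn(self):
        from sklearn.decomposition import PCA

        m = self._matrix()
        x = m.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
        ref = PCA(n_components=3).fit(z.T)
        scores, frac = rd.pca_samples(m)
        np.testing.assert_allclose(
            np.abs(scores.to_numpy()[:, :3]),
            np.abs(ref.transform(z.T)),
            atol=1e-8,
        )


class TestOverrepresentation:
    def test_query_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = rd.overrepresentation_test(universe, {"all": universe}, universe)
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_closed_form_hypergeometric(self):
        universe = {f"g{i}" for i in range(20)}
        ann = {f"g{i}" for i in range(5)}
        out = rd.overrepresentation_test(ann, {"set": ann}, universe)
        from math import comb

        assert out.loc["set", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_small_overlap_excluded_from_report(self):
        universe = {f"g{i}" for i in range(100)}
        ann = {"g0", "g1"}
        out = rd.overrepresentation_test(
            {"g0", "g1", "g2"}, {"tiny": ann}, universe
        )
        assert out.loc["tiny", "overlap"] == 2
        assert not bool(out.loc["tiny", "reported"])

    def test_empty_universe_rejected(self):
        with pytest.raises(DEInputError):
            rd.overrepresentation_test(set(), {}, set())


class TestDegTableRecovery:
    def test_planted_regulon_recovered_with_high_recall(self):
        # gene-level noise 0.3, 4 replicates, fixed seed: the planted
        # regulon is recovered by the FC + q filter and false positives
        # respect the FDR (TF-activity noise off: this checks the DE filter
        # against the stated gene-level noise, not regulator variability)
        cfg = rd.SyntheticConfig(
            n_tfs=10, n_genes=200, regulon_size=10,
            replicates_per_condition=4, noise_sd=0.3,
            activity_cv=0.0, induced_activity_cv=0.0, seed=21,
        )
        prior = rd.generate_prior_truth(cfg)
        expr, truth = rd.generate_expression(prior, cfg)
        de_cfg = DEConfig()
        deg = build_deg_table(expr, de_cfg)
        passed = set(rd.filter_degs(deg, de_cfg).index)
        regulon = {g for _, g in truth.differential_edges}
        recall = len(passed & regulon) / len(regulon)
        assert recall >= 0.9
        false = passed - regulon
        # non-regulon discoveries are limited; allow binomial slack around q
        assert len(false) <= max(5, 0.05 * len(passed))
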