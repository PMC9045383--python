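import numpy as np
import pandas as pd
import pytest

from microdyn.diversity import (
    alpha_diversity,
    between_subject_distances,
    convergence_test,
    kruskal_wallis,
    unifrac_matrix,
    weighted_unifrac,
)
from microdyn.io import parse_newick
from microdyn.synthetic import generate_tree


def brute_force_weighted_unifrac(p, q, tree, normalized):
    """Oracle: explicit per-branch accumulation via tip descendant sets."""
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        P = sum(p.get(t, 0.0) for t in tips)
        Q = sum(q.get(t, 0.0) for t in tips)
        num += (node.length or 0.0) * abs(P - Q)
        den += (node.length or 0.0) * (P + Q)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


class TestAlphaDiversity:
    def test_single_otu_shannon_zero(self, toy_table):
        sub = toy_table.counts[["B1"]]
        from microdyn.io import OtuTable

        table = OtuTable(sub, toy_table.metadata.loc[["B1"]])
        assert alpha_diversity(table, "shannon")["B1"] == pytest.approx(0.0)

    def test_equal_abundances_give_log_k(self):
        from microdyn.io import OtuTable

        counts = pd.DataFrame({"s": [10, 10, 10, 10]}, index=list("abcd"))
        meta = pd.DataFrame(
            {"subject": ["A"], "time_point": [1], "phase": [1],
             "environment": ["outside"], "gender": ["male"]}, index=["s"],
        )
        table = OtuTable(counts, meta)
        assert alpha_diversity(table, "shannon")["s"] == pytest.approx(np.log(4))

    def test_observed_otus(self, toy_table):
        obs = alpha_diversity(toy_table, "observed_otus")
        assert obs["A1"] == 2
        assert obs["B1"] == 1


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self):
        tree = parse_newick("(A:1,B:1):0;")
        p = {"A": 0.4, "B": 0.6}
        assert weighted_unifrac(p, p, tree) == pytest.approx(0.0)

    def test_two_leaf_hand_example(self):
        tree = parse_newick("(A:1,B:1):0;")
        p, q = {"A": 1.0, "B": 0.0}, {"A": 0.0, "B": 1.0}
        assert weighted_unifrac(p, q, tree, normalized=False) == pytest.approx(2.0)
        assert weighted_unifrac(p, q, tree, normalized=True) == pytest.approx(1.0)

    def test_three_leaf_internal_branch_cancels(self):
        tree = parse_newick("(A:1,(B:0.5,C:0.5):0.5):0;")
        p = {"A": 0.0, "B": 1.0, "C": 0.0}
        q = {"A": 0.0, "B": 0.0, "C": 1.0}
        assert weighted_unifrac(p, q, tree, normalized=False) == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_brute_force_on_random_trees(self, rng, normalized):
        for i in range(50):
            n = int(rng.integers(3, 11))
            tree = generate_tree(n, seed=1000 + i)
            leaves = [t.name for t in tree.tips()]
            pv, qv = rng.dirichlet(np.ones(n), size=2)
            p = dict(zip(leaves, pv))
            q = dict(zip(leaves, qv))
            mine = weighted_unifrac(p, q, tree, normalized=normalized)
            oracle = brute_force_weighted_unifrac(p, q, tree, normalized)
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_normalized_bounded_in_unit_interval(self, rng):
        tree = generate_tree(8, seed=7)
        leaves = [t.name for t in tree.tips()]
        for _ in range(20):
            p, q = rng.dirichlet(np.ones(8), size=2)
            d = weighted_unifrac(dict(zip(leaves, p)), dict(zip(leaves, q)), tree)
            assert 0.0 <= d <= 1.0

    def test_agrees_with_skbio(self, small_cohort):
        from skbio.diversity import beta_diversity

        table = small_cohort.otu_table
        mine = unifrac_matrix(table, small_cohort.tree, normalized=False)
        ref = beta_diversity(
            "weighted_unifrac", table.counts.T.to_numpy(), ids=table.sample_ids,
            taxa=table.otu_ids, tree=small_cohort.tree, normalized=False,
        )
        assert np.abs(mine.data - ref.data).max() < 1e-9

    def test_unknown_leaf_rejected(self):
        tree = parse_newick("(A:1,B:1):0;")
        with pytest.raises(ValueError, match="ghost"):
            weighted_unifrac({"A": 0.5, "ghost": 0.5}, {"A": 1.0}, tree)


class TestBetweenSubjectDistances:
    def test_pair_counts(self, default_cohort):
        dm = unifrac_matrix(default_cohort.otu_table, default_cohort.tree)
        by_tp = between_subject_distances(
            dm, default_cohort.otu_table.metadata, "time_point"
        )
        # 4 subjects at every time point -> C(4,2) = 6 pairs
        assert all(len(v) == 6 for v in by_tp.values())
        by_phase = between_subject_distances(
            dm, default_cohort.otu_table.metadata, "phase"
        )
        # phase pools its time points' pairs: 5*6, 8*6, 5*6
        assert [len(by_phase[k]) for k in sorted(by_phase)] == [30, 48, 30]

    def test_single_subject_stratum_empty_with_warning(self, toy_table, caplog):
        import logging

        ids = ["A1", "A2"]
        dm_vals = np.array([[0.0, 0.3], [0.3, 0.0]])
        from skbio import DistanceMatrix

        dm = DistanceMatrix(dm_vals, ids=ids)
        with caplog.at_level(logging.WARNING):
            out = between_subject_distances(dm, toy_table.metadata.loc[ids], "phase")
        assert all(v == [] for v in out.values())
        assert "subjects" in caplog.text


class TestKruskalWallis:
    def test_hand_example_no_ties(self):
        res = kruskal_wallis({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.H == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups(self):
        res = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.H == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=0.01)

    def test_bonferroni_multiplication(self):
        groups = {f"g{i}": list(np.random.default_rng(i).normal(size=5))
                  for i in range(5)}
        res = kruskal_wallis(groups)
        n_pairs = 10
        for pair, praw in res.pairwise_p.items():
            assert res.pairwise_p_adjusted[pair] == pytest.approx(
                min(praw * n_pairs, 1.0)
            )
            assert res.pairwise_p_adjusted[pair] >= praw

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})

    def test_agrees_with_scipy(self, rng):
        from scipy import stats

        a, b, c = rng.normal(size=(3, 12))
        res = kruskal_wallis({"a": list(a), "b": list(b), "c": list(c)})
        H, p = stats.kruskal(a, b, c)
        assert res.H == pytest.approx(H)
        assert res.p == pytest.approx(p)
        assert res.df == 2


class TestConvergence:
    def test_shared_environment_detected(self, default_cohort):
        dm = unifrac_matrix(default_cohort.otu_table, default_cohort.tree)
        kw, medians = convergence_test(dm, default_cohort.otu_table.metadata)
        assert kw.p < 0.05
        assert medians["2"] == min(medians.values())
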