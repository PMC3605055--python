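import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import hypergeom

from parsnet import (
    bray_curtis,
    build_network,
    build_reaction_graph,
    differential_reactions,
    distance_matrix,
    euclidean_marginal_distance,
    fisher_presence_test,
    jaccard_distance,
    reaction_chains,
    two_sample_ttest,
    ward_cluster,
)


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        x = {"k1": 3.0, "k2": 1.0}
        assert bray_curtis(x, x) == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        assert bray_curtis({"k1": 2.0}, {"k2": 5.0}) == pytest.approx(1.0)

    def test_worked_example(self):
        x = {"a": 2.0, "b": 0.0, "c": 1.0}
        y = {"a": 1.0, "b": 1.0, "c": 0.0}
        # C = min(2,1) = 1; S_x = 3, S_y = 2 -> 1 - 2/5
        assert bray_curtis(x, y) == pytest.approx(0.6)

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(11)
        keys = [f"k{i}" for i in range(20)]
        for _ in range(20):
            xv = rng.integers(0, 10, len(keys)).astype(float)
            yv = rng.integers(0, 10, len(keys)).astype(float)
            if xv.sum() + yv.sum() == 0:
                continue
            ours = bray_curtis(dict(zip(keys, xv)), dict(zip(keys, yv)))
            assert ours == pytest.approx(scipy_braycurtis(xv, yv))

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis({"a": 0.0}, {"b": 0.0})


class TestJaccard:
    def test_basic_values(self):
        assert jaccard_distance({"r1"}, {"r1"}) == 0.0
        assert jaccard_distance({"r1"}, {"r2"}) == 1.0
        assert jaccard_distance({"r1", "r2"}, {"r2", "r3"}) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard_distance(set(), set())

    def test_triangle_inequality_on_random_sets(self):
        rng = np.random.default_rng(5)
        universe = list(range(12))
        sets = [
            {u for u in universe if rng.random() < 0.5} or {0} for _ in range(12)
        ]
        for a, b, c in itertools.combinations(sets, 3):
            assert jaccard_distance(a, c) <= (
                jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
            )


class TestEuclideanMarginal:
    def test_identical_profiles_zero(self):
        p = {"r1": 0.4, "r2": 0.9}
        assert euclidean_marginal_distance(p, p) == 0.0

    def test_orthogonal_unit_profiles(self):
        assert euclidean_marginal_distance(
            {"r1": 1.0}, {"r2": 1.0}
        ) == pytest.approx(math.sqrt(2))

    def test_absent_reactions_impute_zero(self):
        assert euclidean_marginal_distance(
            {"r1": 0.6}, {"r1": 0.6, "r2": 0.8}
        ) == pytest.approx(0.8)


class TestWardClustering:
    def test_two_samples_single_merge(self):
        dm = distance_matrix({"s1": {"e1"}, "s2": {"e2"}}, "jaccard")
        dendro = ward_cluster(dm)
        assert dendro.linkage_matrix.shape == (1, 4)
        assert dendro.cut(2) == {"s1": 1, "s2": 2} or dendro.cut(2) == {
            "s1": 2,
            "s2": 1,
        }

    def test_closest_pair_merges_first(self):
        from parsnet.comparative import DistanceMatrix

        m = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dendro = ward_cluster(DistanceMatrix(("a", "b", "c"), m))
        first = dendro.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_newick_roundtrip_parseable(self, tmp_path):
        import dendropy

        from parsnet.comparative import DistanceMatrix

        m = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dendro = ward_cluster(DistanceMatrix(("a", "b", "c"), m))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_invalid_matrix_rejected(self):
        from parsnet.comparative import DistanceMatrix

        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestFisher:
    def test_extreme_split_six_vs_six(self):
        # 6/6 present vs 0/6: only the two fully-polarized tables are as
        # improbable as observed -> p = 2 / C(12,6)
        assert fisher_presence_test(6, 6, 0, 6) == pytest.approx(2 / 924, rel=1e-9)

    def test_identical_proportions_p_one(self):
        assert fisher_presence_test(3, 6, 3, 6) == pytest.approx(1.0)
        assert fisher_presence_test(6, 6, 6, 6) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_small_sweep(self):
        # independent oracle: sum hypergeometric point probabilities of all
        # tables with the observed margins that are no more probable
        for n1, n2 in [(4, 4), (5, 3), (6, 6)]:
            for a in range(n1 + 1):
                for b in range(n2 + 1):
                    k = a + b
                    support = range(max(0, k - n2), min(n1, k) + 1)
                    p_obs = hypergeom.pmf(a, n1 + n2, k, n1)
                    expected = sum(
                        hypergeom.pmf(x, n1 + n2, k, n1)
                        for x in support
                        if hypergeom.pmf(x, n1 + n2, k, n1) <= p_obs * (1 + 1e-9)
                    )
                    assert fisher_presence_test(a, n1, b, n2) == pytest.approx(
                        min(expected, 1.0), rel=1e-8
                    )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_presence_test(0, 0, 1, 6)


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_case(self):
        res = two_sample_ttest([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.pvalue == pytest.approx(0.0213, abs=5e-4)

    def test_label_swap_antisymmetry(self):
        a, b = [0.1, 0.5, 0.2], [0.6, 0.3, 0.9, 0.8]
        r1, r2 = two_sample_ttest(a, b), two_sample_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_zero_pooled_variance_flagged_not_silent(self):
        res = two_sample_ttest([1.0, 1.0], [1.0, 1.0])
        assert res.degenerate
        assert math.isnan(res.pvalue)


class TestDifferentialReactions:
    def test_presence_shift_caught_by_fisher(self):
        g1 = {f"s{i}": {"rA": 0.9, "rB": 0.5} for i in range(6)}
        g2 = {f"t{i}": {"rB": 0.5 + 0.001 * i} for i in range(6)}
        comp = differential_reactions(g1, g2)
        row = comp.table.loc["rA"]
        assert row["fisher_p"] == pytest.approx(2 / 924, rel=1e-6)
        assert "rA" in comp.fisher_significant

    def test_marginal_shift_with_identical_presence_is_ttest_only(self):
        # present everywhere in both groups -> Fisher p = 1; only the
        # marginal t-test can see the shifted likelihoods
        g1 = {f"s{i}": {"rA": 0.8 + 0.01 * i} for i in range(6)}
        g2 = {f"t{i}": {"rA": 0.2 + 0.01 * i} for i in range(6)}
        comp = differential_reactions(g1, g2)
        row = comp.table.loc["rA"]
        assert row["fisher_p"] == 1.0
        assert row["t_p"] < 0.05
        assert comp.ttest_only == {"rA"}
        assert row["fold_change"] == pytest.approx(row["mean_p_group1"] / row["mean_p_group2"])

    def test_bh_correction_is_less_permissive(self):
        rng = np.random.default_rng(3)
        g1 = {f"s{i}": {f"r{j}": rng.random() for j in range(40)} for i in range(4)}
        g2 = {f"t{i}": {f"r{j}": rng.random() for j in range(40)} for i in range(4)}
        raw = differential_reactions(g1, g2)
        adj = differential_reactions(g1, g2, correction="bh")
        assert adj.ttest_significant <= raw.ttest_significant

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            differential_reactions({"s": {}}, {"t": {}, "u": {}})


class TestReactionGraph:
    @pytest.fixture()
    def chain_net(self):
        return build_network(
            {"r1": {"A", "B"}, "r2": {"B", "C"}, "r3": {"D", "E"}},
            {"e1": {"r1", "r2", "r3"}},
        )

    def test_shared_metabolite_edges_and_components(self, chain_net):
        g = build_reaction_graph(["r1", "r2", "r3"], chain_net)
        assert set(g.edges) == {("r1", "r2")}
        comps = reaction_chains(g)
        assert [c.members for c in comps] == [("r1", "r2"), ("r3",)]

    def test_single_reaction_graph(self, chain_net):
        g = build_reaction_graph(["r3"], chain_net)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_currency_metabolite_exclusion_breaks_edges(self, chain_net):
        g = build_reaction_graph(["r1", "r2", "r3"], chain_net, exclude_metabolites={"B"})
        assert g.number_of_edges() == 0
        assert len(reaction_chains(g)) == 3

    def test_unknown_reaction_rejected(self, chain_net):
        with pytest.raises(KeyError):
            build_reaction_graph(["r9"], chain_net)

    def test_chain_flags_propagate(self, chain_net):
        g = build_reaction_graph(["r1", "r2", "r3"], chain_net)
        chains = reaction_chains(g, ttest_only={"r1", "r2"}, both_significant={"r3"})
        assert chains[0].only_marginal_evidence
        assert not chains[1].only_marginal_evidence
        assert chains[1].both_sig_members == ("r3",)
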