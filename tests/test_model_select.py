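import math

import numpy as np
import pytest

from phylocombine import (
    GTRParams,
    combinability_rank,
    concatenate_supermatrix,
    count_free_parameters,
    fit_linked_scheme,
    information_criteria,
    sample_tree,
    simulate_alignment,
    sum_fit_summaries,
)
from phylocombine.model_select import (
    FitSummary,
    cluster_mix_summary,
    greedy_merge_partitions,
    starting_tree,
)
from phylocombine.partitions import Partition, PartitionScheme

GTR_FREE = frozenset({"exchangeabilities", "base_freqs"})


class TestParameterCounting:
    def test_organellar_separate_trees_convention(self):
        # two edge-proportional gene sets on the full taxon sampling
        k = count_free_parameters(
            [("edge_proportional", 79, 226), ("edge_proportional", 39, 226)]
        )
        assert k == 2194

    def test_single_proportional_entries(self):
        assert count_free_parameters([("edge_proportional", 79, 226)]) == 1317
        assert count_free_parameters([("edge_proportional", 39, 226)]) == 877
        assert count_free_parameters([("edge_proportional", 118, 226)]) == 1746

    def test_unpartitioned_minimal(self):
        assert count_free_parameters([("unpartitioned", 1, 4)]) == 15

    def test_unlinked_equals_separate(self):
        unlinked = count_free_parameters([("edge_unlinked", 2, 6)])
        separate = count_free_parameters(
            [("edge_proportional", 1, 6), ("edge_proportional", 1, 6)]
        )
        assert unlinked == separate == 38

    def test_strictly_increasing_along_nesting(self):
        for p in (2, 5, 79):
            for t in (4, 10, 226):
                ks = [
                    count_free_parameters([(s, p, t)])
                    for s in ("edge_equal", "edge_proportional", "edge_unlinked")
                ]
                k0 = count_free_parameters([("unpartitioned", 1, t)])
                assert k0 < ks[0] < ks[1] < ks[2]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_free_parameters([("edge_equal", 0, 6)])
        with pytest.raises(ValueError):
            count_free_parameters([("nonsense", 2, 6)])


class TestInformationCriteria:
    def test_separate_topology_worked_values(self):
        ic = information_criteria(-3034134.6942, 2194, 162101)
        assert ic.BIC == pytest.approx(6094588.557, abs=0.01)
        assert ic.AICc == pytest.approx(6072717.621, abs=0.01)

    def test_direct_arithmetic(self):
        ic = information_criteria(-100.0, 2, 100)
        assert ic.AIC == pytest.approx(204.0)
        assert ic.AICc == pytest.approx(204.0 + 12.0 / 97.0)
        assert ic.BIC == pytest.approx(2 * math.log(100) + 200)

    def test_zero_parameter_limit(self):
        ic = information_criteria(-50.0, 0, 10)
        assert ic.AIC == ic.BIC == 100.0
        assert ic.AICc == ic.AIC

    def test_aicc_undefined(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 5, 6)

    @pytest.mark.parametrize(
        "k,n,bic,aicc",
        [
            (1317, 103806, 4772954.87, 4760411.026),
            (877, 58295, 1320149.795, 1312307.058),
            (1746, 162101, 6130820.047, 6113405.119),
        ],
    )
    def test_bic_aicc_gap_depends_only_on_k_and_n(self, k, n, bic, aicc):
        # the gap BIC - AICc is k(ln n - 2) - 2k(k+1)/(n-k-1), free of lnL
        gap = k * (math.log(n) - 2.0) - 2.0 * k * (k + 1.0) / (n - k - 1.0)
        assert gap == pytest.approx(bic - aicc, abs=0.05)


class TestCombinabilityRank:
    def _fit(self, lnl, k, n, scheme="edge_equal"):
        return FitSummary(lnl, k, n, scheme)

    def test_single_candidate_ranks_first(self):
        df = combinability_rank([("only", self._fit(-100, 5, 1000))])
        assert df.iloc[0]["label"] == "only"
        assert bool(df.iloc[0]["best_BIC"]) and bool(df.iloc[0]["best_AICc"])

    def test_separate_trees_summation_rule(self):
        parts = [self._fit(-2322498.5708, 1317, 103806),
                 self._fit(-711636.1234, 877, 58295)]
        df = combinability_rank([("sep", parts)])
        row = df.iloc[0]
        assert row["lnL"] == pytest.approx(sum(f.lnL for f in parts))
        assert row["k"] == 2194
        assert row["n"] == 162101

    def test_input_order_invariance(self):
        cands = [
            ("a", self._fit(-120, 5, 1000)),
            ("b", self._fit(-100, 8, 1000)),
            ("c", self._fit(-110, 6, 1000)),
        ]
        df1 = combinability_rank(cands)
        df2 = combinability_rank(list(reversed(cands)))
        assert df1["label"].tolist() == df2["label"].tolist()

    def test_inconsistent_n_rejected(self):
        with pytest.raises(ValueError, match="site totals"):
            combinability_rank(
                [("a", self._fit(-100, 5, 1000)), ("b", self._fit(-90, 5, 900))]
            )


@pytest.fixture(scope="module")
def two_gene_data():
    tree = sample_tree(6, seed=21, mean_branch_length=0.1)
    p = GTRParams(rates=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0), freqs=(0.3, 0.2, 0.2, 0.3))
    fast = tree.copy()
    for n in fast.edges():
        n.length *= 2.0
    g1 = simulate_alignment(tree, p, 400, seed=22)
    g2 = simulate_alignment(fast, p, 400, seed=23)
    comb, scheme = concatenate_supermatrix([g1, g2], ["slow", "fast"])
    return tree, comb, scheme


class TestLinkedFits:

    def test_proportional_nests_equal(self, two_gene_data):
        tree, comb, scheme = two_gene_data
        equal = fit_linked_scheme(
            comb, scheme, "edge_equal", topology=tree, free=GTR_FREE
        )
        prop = fit_linked_scheme(
            comb, scheme, "edge_proportional", topology=tree, free=GTR_FREE,
            init_from=equal,
        )
        assert prop.lnL >= equal.lnL - 1e-3
        # multipliers satisfy the site-weighted mean-1 constraint
        w = np.array([p.n_sites for p in scheme.partitions], dtype=float)
        assert np.dot(w, prop.multipliers) / w.sum() == pytest.approx(1.0, abs=1e-9)
        # the 2x-rate gene gets the larger multiplier
        assert prop.multipliers[1] > prop.multipliers[0]

    def test_k_and_n_bookkeeping(self, two_gene_data):
        tree, comb, scheme = two_gene_data
        fit = fit_linked_scheme(
            comb, scheme, "edge_equal", topology=tree, free=GTR_FREE
        )
        # 8 substitution params per partition (5 exch + 3 freqs), 9 edges
        assert fit.k == 8 * 2 + (2 * 6 - 3)
        assert fit.n == 800
        assert len(fit.per_partition_lnL) == 2
        assert fit.lnL == pytest.approx(sum(fit.per_partition_lnL), abs=1e-8)

    def test_tree_length_scales_with_rate(self, two_gene_data):
        tree, comb, scheme = two_gene_data
        prop = fit_linked_scheme(
            comb, scheme, "edge_proportional", topology=tree, free=GTR_FREE
        )
        assert prop.tree_lengths[1] > prop.tree_lengths[0]


class TestGreedyMerge:
    def test_single_partition_unchanged(self):
        tree = sample_tree(5, seed=1, mean_branch_length=0.1)
        aln = simulate_alignment(tree, GTRParams(), 200, seed=2)
        scheme = PartitionScheme([Partition("g1", [(0, 200)])])
        merged, trace = greedy_merge_partitions(
            aln, scheme, tree, free=frozenset({"base_freqs"})
        )
        assert merged.names == ["g1"]
        assert trace.empty

    def test_identical_process_merges(self):
        tree = sample_tree(6, seed=3, mean_branch_length=0.1)
        p = GTRParams()
        alns = [simulate_alignment(tree, p, 300, seed=10 + i) for i in range(3)]
        comb, scheme = concatenate_supermatrix(alns, ["g1", "g2", "g3"])
        merged, trace = greedy_merge_partitions(
            comb, scheme, tree, free=frozenset({"base_freqs"})
        )
        assert merged.n_partitions == 1
        assert (trace["criterion_delta"] < 0).all()

    def test_distinct_frequency_groups_do_not_mix(self):
        tree = sample_tree(6, seed=4, mean_branch_length=0.1)
        p1 = GTRParams(freqs=(0.4, 0.1, 0.1, 0.4))
        p2 = GTRParams(freqs=(0.1, 0.4, 0.4, 0.1))
        alns = [simulate_alignment(tree, p1, 300, seed=s) for s in (20, 21)] + [
            simulate_alignment(tree, p2, 300, seed=s) for s in (22, 23)
        ]
        comb, scheme = concatenate_supermatrix(alns, ["a1", "a2", "b1", "b2"])
        merged, _ = greedy_merge_partitions(
            comb, scheme, tree, free=frozenset({"base_freqs"})
        )
        mix = cluster_mix_summary(
            merged, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert not mix["mixed"].any()


class TestClusterMix:
    def test_counts(self):
        scheme = PartitionScheme(
            [Partition("p1+p2", [(0, 10)]), Partition("m1", [(10, 20)])]
        )
        df = cluster_mix_summary(scheme, {"p1": "p", "p2": "p", "m1": "m"})
        assert df["mixed"].tolist() == [False, False]
        assert df["singleton_tag"].tolist() == [None, "m"]

    def test_mixed_cluster(self):
        scheme = PartitionScheme([Partition("p1+m1", [(0, 10)])])
        df = cluster_mix_summary(scheme, {"p1": "p", "m1": "m"})
        assert df["mixed"].tolist() == [True]

    def test_unlabeled_partition_rejected(self):
        scheme = PartitionScheme([Partition("x", [(0, 10)])])
        with pytest.raises(ValueError, match="unlabeled"):
            cluster_mix_summary(scheme, {"y": "p"})


def test_starting_tree_reasonable():
    from phylocombine import rf_distance

    tree = sample_tree(8, seed=31, mean_branch_length=0.1)
    aln = simulate_alignment(tree, GTRParams(), 4000, seed=32)
    start = starting_tree(aln)
    assert start.leaf_set() == tree.leaf_set()
    assert rf_distance(start, tree) <= 4
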