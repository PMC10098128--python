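import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

from phylocombine import (
    GTRParams,
    bootstrap_support,
    build_rate_matrix,
    discrete_gamma_rates,
    fit_model,
    nni_search,
    parse_newick,
    per_partition_contributions,
    simulate_alignment,
    sample_tree,
    transition_matrix,
    tree_log_likelihood,
)
from phylocombine.alignment import NucAlignment
from phylocombine.likelihood import TreeLikelihood, _EigenGTR, nni_neighbors
from phylocombine.partitions import Partition, PartitionScheme
from phylocombine.tree import Node, Tree

from conftest import enumeration_loglik, random_gtr


class TestRateMatrix:
    def test_jc_symmetry(self, jc):
        Q = build_rate_matrix(jc)
        assert np.allclose(np.diag(Q), -1.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_detailed_balance_and_normalization(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_gtr(rng)
            Q = build_rate_matrix(p)
            pi = np.asarray(p.freqs)
            flux = pi[:, None] * Q
            assert np.allclose(flux, flux.T, atol=1e-12)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            assert np.isclose(-np.dot(pi, np.diag(Q)), 1.0, atol=1e-12)

    def test_eigen_path_matches_expm(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_gtr(rng)
            Q = build_rate_matrix(p)
            eig = _EigenGTR(p)
            t = float(np.exp(rng.uniform(-6, 2)))
            assert np.allclose(eig.pmat(t), expm(Q * t), atol=1e-9)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, gtr_params):
        Q = build_rate_matrix(gtr_params)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(4))

    def test_stationarity_at_long_times(self, gtr_params):
        Q = build_rate_matrix(gtr_params)
        P = transition_matrix(Q, 1e4)
        for row in P:
            assert np.allclose(row, gtr_params.freqs, atol=1e-8)

    def test_jc_closed_form(self, jc):
        Q = build_rate_matrix(jc)
        t = 0.1
        P = transition_matrix(Q, t)
        expected = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        assert P[0, 0] == pytest.approx(expected, abs=1e-10)
        assert P[0, 0] == pytest.approx(0.90638, abs=1e-5)

    def test_negative_time_rejected(self, jc):
        with pytest.raises(ValueError):
            transition_matrix(build_rate_matrix(jc), -0.1)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(2.0, 1).tolist() == [1.0]

    def test_low_heterogeneity_limit(self):
        rates = discrete_gamma_rates(100.0, 4)
        assert np.all(np.abs(rates - 1.0) < 0.2)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.7])
    def test_matches_quadrature_oracle(self, alpha):
        n = 4
        dist = stats.gamma(a=alpha, scale=1.0 / alpha)
        bounds = dist.ppf(np.arange(n + 1) / n)
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            hi_eff = hi if np.isfinite(hi) else dist.ppf(1 - 1e-12)
            mass, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi_eff)
            expected.append(n * mass)
        got = discrete_gamma_rates(alpha, n)
        assert np.allclose(got, expected, atol=1e-3)
        assert np.all(np.diff(got) > 0)
        assert np.isclose(got.mean(), 1.0, atol=1e-9)


def _two_tip_tree(t1: float, t2: float) -> Tree:
    root = Node()
    root.add_child(Node("a", t1))
    root.add_child(Node("b", t2))
    return Tree(root)


class TestTreeLogLikelihood:
    def test_two_taxon_closed_form(self, jc):
        tree = _two_tip_tree(0.05, 0.05)
        aln = NucAlignment(["a", "b"], ["A", "A"])
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-4.0 * 0.1 / 3.0)))
        assert tree_log_likelihood(tree, aln, jc) == pytest.approx(expected, abs=1e-12)

    def test_all_gap_column_contributes_zero(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.1);")
        aln = NucAlignment(["a", "b", "c", "d"], ["ACG", "AGG", "TCG", "ACT"])
        with_gap = NucAlignment(
            ["a", "b", "c", "d"], ["ACG-", "AGG-", "TCG-", "ACT-"]
        )
        l1 = tree_log_likelihood(tree, aln, gtr_params)
        l2 = tree_log_likelihood(tree, with_gap, gtr_params)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_duplicated_column_adds_its_contribution(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.1);")
        aln = NucAlignment(["a", "b", "c", "d"], ["ACG", "AGG", "TCG", "ACT"])
        dup = NucAlignment(["a", "b", "c", "d"], ["ACGG", "AGGG", "TCGG", "ACTT"])
        one = NucAlignment(["a", "b", "c", "d"], ["G", "G", "G", "T"])
        assert tree_log_likelihood(tree, dup, gtr_params) == pytest.approx(
            tree_log_likelihood(tree, aln, gtr_params)
            + tree_log_likelihood(tree, one, gtr_params),
            abs=1e-9,
        )

    @pytest.mark.parametrize("with_rate_classes", [False, True])
    def test_matches_enumeration_oracle(self, with_rate_classes):
        rng = np.random.default_rng(11 if with_rate_classes else 10)
        for _ in range(10):
            n_taxa = int(rng.integers(4, 6))
            tree = sample_tree(n_taxa, int(rng.integers(2**31)), 0.15)
            p = random_gtr(rng)
            if with_rate_classes:
                from dataclasses import replace

                p = replace(p, alpha=float(rng.uniform(0.3, 2.0)),
                            p_inv=float(rng.uniform(0.0, 0.4)), n_cat=3)
            aln = simulate_alignment(tree, p, 20, int(rng.integers(2**31)))
            assert tree_log_likelihood(tree, aln, p) == pytest.approx(
                enumeration_loglik(tree, aln, p), abs=1e-9
            )

    def test_invariant_to_rerooting(self, gtr_params):
        from phylocombine import midpoint_root

        tree = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,e:0.2):0.1,d:0.1);")
        aln = NucAlignment(
            ["a", "b", "c", "d", "e"],
            ["ACGTA", "AGGTA", "TCGTC", "ACTTA", "GCGTA"],
        )
        rerooted = midpoint_root(tree)
        assert tree_log_likelihood(tree, aln, gtr_params) == pytest.approx(
            tree_log_likelihood(rerooted, aln, gtr_params), abs=1e-9
        )

    def test_invariant_to_child_order(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.1);")
        flipped = tree.copy()
        for node in flipped.preorder():
            node.children.reverse()
        aln = NucAlignment(["a", "b", "c", "d"], ["ACG", "AGG", "TCG", "ACT"])
        assert tree_log_likelihood(tree, aln, gtr_params) == pytest.approx(
            tree_log_likelihood(flipped, aln, gtr_params), abs=1e-10
        )

    def test_pattern_compression_consistency(self, gtr_params):
        # repeated columns hit the compressed path; spell the same data as
        # an explicit per-site sum of single-column likelihoods
        tree = parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.1);")
        rng = np.random.default_rng(5)
        cols = ["".join(rng.choice(list("ACGT-"), 4)) for _ in range(6)]
        cols = cols + cols  # force multiplicity
        seqs = ["".join(c[i] for c in cols) for i in range(4)]
        aln = NucAlignment(["a", "b", "c", "d"], seqs)
        persite = sum(
            tree_log_likelihood(
                tree, NucAlignment(["a", "b", "c", "d"], [c[i] for i in range(4)]), gtr_params
            )
            for c in cols
        )
        assert tree_log_likelihood(tree, aln, gtr_params) == pytest.approx(
            persite, abs=1e-9
        )


class TestFitModel:
    def test_two_taxon_jc_distance_closed_form(self, jc):
        rng = np.random.default_rng(1)
        tree = _two_tip_tree(0.2, 0.2)
        aln = simulate_alignment(tree, jc, 5000, seed=4)
        mismatch = np.mean(
            [x != y for x, y in zip(aln.sequences[0], aln.sequences[1])]
        )
        expected = -0.75 * np.log(1.0 - 4.0 * mismatch / 3.0)
        res = fit_model(tree, aln, jc, free={"branch_lengths"})
        fitted_total = sum(n.length for n in res.tree.edges())
        assert fitted_total == pytest.approx(expected, abs=1e-3)

    def test_refit_at_optimum_is_stable(self, gtr_params):
        tree = sample_tree(6, seed=2, mean_branch_length=0.1)
        aln = simulate_alignment(tree, gtr_params, 500, seed=3)
        res = fit_model(tree, aln, gtr_params, tol=1e-4)
        res2 = fit_model(res.tree, aln, res.params, tol=1e-4)
        assert res2.lnL == pytest.approx(res.lnL, abs=1e-2)
        assert res2.lnL >= res.lnL - 1e-4

    def test_parameter_recovery(self):
        truth = GTRParams(
            rates=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0),
            freqs=(0.35, 0.15, 0.15, 0.35),
            alpha=0.7,
            n_cat=4,
        )
        tree = sample_tree(8, seed=1, mean_branch_length=0.1)
        aln = simulate_alignment(tree, truth, 10000, seed=2)
        res = fit_model(tree, aln, GTRParams(n_cat=4), tol=1e-3, max_rounds=30)
        assert res.params.alpha == pytest.approx(0.7, abs=0.15)
        assert np.allclose(res.params.freqs, truth.freqs, atol=0.02)


class TestNNISearch:
    def test_true_topology_is_local_optimum(self, gtr_params):
        from phylocombine import rf_distance

        tree = sample_tree(6, seed=9, mean_branch_length=0.12)
        aln = simulate_alignment(tree, gtr_params, 5000, seed=10)
        found = nni_search(tree, aln, gtr_params)
        assert rf_distance(found, tree) == 0

    def test_recovers_truth_from_one_nni_away(self, gtr_params):
        from phylocombine import perturb_nni, rf_distance

        successes = 0
        n_reps = 20
        for rep in range(n_reps):
            tree = sample_tree(6, seed=100 + rep, mean_branch_length=0.12)
            aln = simulate_alignment(tree, gtr_params, 5000, seed=200 + rep)
            start = perturb_nni(tree, 1, seed=300 + rep)
            found = nni_search(start, aln, gtr_params)
            successes += rf_distance(found, tree) == 0
        assert successes >= 18

    def test_lnl_trace_strictly_increasing(self, gtr_params):
        from phylocombine import perturb_nni

        tree = sample_tree(6, seed=42, mean_branch_length=0.12)
        aln = simulate_alignment(tree, gtr_params, 2000, seed=43)
        start = perturb_nni(tree, 2, seed=44)
        _, trace = nni_search(start, aln, gtr_params, return_trace=True)
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_neighbor_count(self):
        tree = sample_tree(6, seed=0, mean_branch_length=0.1)
        # an unrooted 6-tip binary tree has 3 internal edges, 2 NNIs each
        assert len(nni_neighbors(tree)) == 6


class TestBootstrap:
    def test_single_replicate_supports_binary(self, jc):
        tree = sample_tree(5, seed=1, mean_branch_length=0.2)
        aln = simulate_alignment(tree, jc, 300, seed=2)
        out = bootstrap_support(aln, jc, tree, n_reps=1, seed=3)
        sups = [n.support for n in out.internal_edges() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_deep_split_gets_high_support(self, jc):
        # two clades separated by a long internal edge
        tree = parse_newick(
            "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5,e:0.05);"
        )
        aln = simulate_alignment(tree, jc, 5000, seed=5)
        out = bootstrap_support(aln, jc, tree, n_reps=50, seed=6)
        split_support = {
            frozenset(n.label for n in Tree(x).tips()): x.support
            for x in out.internal_edges()
        }
        assert split_support[frozenset("ab")] >= 95.0

    def test_invariant_to_taxon_input_order(self, jc):
        tree = sample_tree(5, seed=7, mean_branch_length=0.2)
        aln = simulate_alignment(tree, jc, 400, seed=8)
        shuffled = aln.subset_taxa(list(reversed(aln.taxon_labels)))
        a = bootstrap_support(aln, jc, tree, n_reps=10, seed=9)
        b = bootstrap_support(shuffled, jc, tree, n_reps=10, seed=9)
        sup_a = sorted(n.support for n in a.internal_edges() if n.support is not None)
        sup_b = sorted(n.support for n in b.internal_edges() if n.support is not None)
        assert sup_a == sup_b


class TestPerPartitionContributions:
    def test_single_partition_equals_total(self, gtr_params):
        tree = sample_tree(5, seed=3, mean_branch_length=0.1)
        aln = simulate_alignment(tree, gtr_params, 300, seed=4)
        scheme = PartitionScheme([Partition("all", [(0, 300)])])
        contributions = per_partition_contributions(tree, aln, scheme)
        assert len(contributions) == 1
        # the single contribution is the fitted total on the fixed tree
        from phylocombine.likelihood import fit_model as _fit

        ref = _fit(
            tree, aln, GTRParams(),
            free={"exchangeabilities", "base_freqs"}, max_rounds=20,
        )
        assert contributions[0] == pytest.approx(ref.lnL, abs=0.5)

    def test_additivity(self, gtr_params):
        from phylocombine.likelihood import PartitionedLikelihood

        tree = sample_tree(5, seed=5, mean_branch_length=0.1)
        aln = simulate_alignment(tree, gtr_params, 400, seed=6)
        scheme = PartitionScheme(
            [Partition("g1", [(0, 150)]), Partition("g2", [(150, 400)])]
        )
        joint = PartitionedLikelihood(
            tree, aln, scheme, [gtr_params, gtr_params]
        )
        assert joint.total() == pytest.approx(sum(joint.per_partition()), abs=1e-8)

    def test_out_of_bounds_partition(self, gtr_params):
        tree = sample_tree(5, seed=5, mean_branch_length=0.1)
        aln = simulate_alignment(tree, gtr_params, 100, seed=6)
        scheme = PartitionScheme([Partition("g1", [(0, 200)])])
        with pytest.raises(ValueError, match="bounds"):
            per_partition_contributions(tree, aln, scheme)
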