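"""Mk transition probabilities, pruning likelihood against exhaustive
enumeration, branch/shape optimisation, ML search against an exhaustive
topology scan, and ML bootstrap behaviour."""

import itertools
import math

import numpy as np
import pytest

from mkphylo._topo import UTree
from mkphylo.matrix import CharacterMatrix
from mkphylo.mk import (MkModel, MkPruningEngine, MLSearchConfig,
                        bootstrap_ml, discrete_gamma_rates, mk_loglik,
                        mk_transition_prob, ml_search)
from mkphylo.parsimony import enumerate_topologies
from mkphylo.simulate import (GeneratingTreeSpec, SimulationConfig,
                              assemble_matrix, make_generating_tree,
                              recode_binary, recode_multistate,
                              simulate_nucleotides)
from mkphylo.tree import (collapse_by_support, parse_newick, resolution,
                          rf_distance)

from conftest import matrix_from_rows


class TestTransitionProb:
    def test_identity_at_zero_and_uniform_at_infinity(self):
        for k in (2, 4):
            assert np.allclose(mk_transition_prob(k, 0.0), np.eye(k))
            assert np.allclose(mk_transition_prob(k, 500.0),
                               np.full((k, k), 1.0 / k), atol=1e-12)

    def test_binary_closed_form(self):
        P = mk_transition_prob(2, 1.0)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2.0), abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            mk_transition_prob(2, -0.1)

    def test_discrete_gamma_categories_average_to_one(self):
        for alpha in (0.1, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(rates) > 0).all()


def _brute_loglik(tree_newick, matrix, gamma_rates=None):
    """Exhaustive sum over internal-state assignments on a quartet."""
    tree = parse_newick(tree_newick)
    rates = gamma_rates if gamma_rates is not None else np.ones(1)
    internals = [n for n in tree.preorder() if not n.is_leaf]
    row = {name: i for i, name in enumerate(matrix.taxa)}
    total = 0.0
    for j in range(matrix.n_chars):
        k = int(matrix.k_per_char[j])
        L = 0.0
        for r in rates:
            for states in itertools.product(range(k), repeat=len(internals)):
                assign = dict(zip(map(id, internals), states))
                p = 1.0 / k
                ok = True
                for node in tree.preorder():
                    for child in node.children:
                        s_p = assign[id(node)]
                        s_c = (assign[id(child)] if not child.is_leaf
                               else matrix.data[row[child.name], j])
                        p *= mk_transition_prob(k, child.length * r)[s_p, s_c]
                L += p
        total += math.log(L / len(rates))
    return total


class TestPruning:
    NEWICK = "((A:0.3,B:0.7):0.25,(C:0.5,D:0.1):0.4);"

    def test_matches_exhaustive_enumeration_binary(self):
        rng = np.random.default_rng(0)
        m = CharacterMatrix(list("ABCD"), rng.integers(0, 2, (4, 8)).astype(np.int8),
                            np.full(8, 2, dtype=np.int8))
        ours = mk_loglik(parse_newick(self.NEWICK), m, MkModel(gamma_categories=0))
        assert abs(ours - _brute_loglik(self.NEWICK, m)) < 1e-10

    def test_matches_exhaustive_enumeration_multistate_and_gamma(self):
        rng = np.random.default_rng(1)
        m = CharacterMatrix(list("ABCD"), rng.integers(0, 4, (4, 5)).astype(np.int8),
                            np.full(5, 4, dtype=np.int8))
        rates = discrete_gamma_rates(0.6, 4)
        ours = mk_loglik(parse_newick(self.NEWICK), m,
                         MkModel(gamma_categories=4), alpha=0.6)
        assert abs(ours - _brute_loglik(self.NEWICK, m, rates)) < 1e-10

    def test_saturated_branches_approach_independence(self):
        m = matrix_from_rows("ABCD", ["0", "1", "0", "1"])
        long = "((A:50,B:50):50,(C:50,D:50):50);"
        ours = mk_loglik(parse_newick(long), m, MkModel(gamma_categories=0))
        assert abs(ours - _brute_loglik(long, m)) < 1e-10
        # tips independent at saturation: L -> (1/k)^n per character
        assert ours == pytest.approx(4 * math.log(0.5), abs=1e-6)

    def test_duplicating_columns_doubles_loglik(self):
        rng = np.random.default_rng(2)
        m = CharacterMatrix(list("ABCD"), rng.integers(0, 2, (4, 6)).astype(np.int8),
                            np.full(6, 2, dtype=np.int8))
        doubled = CharacterMatrix(list("ABCD"), np.hstack([m.data, m.data]),
                                  np.concatenate([m.k_per_char, m.k_per_char]))
        t = parse_newick(self.NEWICK)
        model = MkModel(gamma_categories=0)
        assert mk_loglik(t, doubled, model) == pytest.approx(
            2 * mk_loglik(t, m, model), abs=1e-9)

    def test_likelihood_invariant_under_rerooting(self):
        rng = np.random.default_rng(3)
        m = CharacterMatrix(list("ABCD"), rng.integers(0, 2, (4, 10)).astype(np.int8),
                            np.full(10, 2, dtype=np.int8))
        a = "((A:0.3,B:0.7):0.25,(C:0.5,D:0.1):0.4);"
        b = "((A:0.3,B:0.7):0.65,C:0.5,D:0.1);"        # same unrooted tree
        for model, alpha in ((MkModel(gamma_categories=0), None),
                             (MkModel(gamma_categories=4), 0.8)):
            assert abs(mk_loglik(parse_newick(a), m, model, alpha) -
                       mk_loglik(parse_newick(b), m, model, alpha)) < 1e-10

    def test_partition_modes_differ_on_mixed_matrices(self):
        # binary characters padded into a 4-state matrix put probability
        # mass on unobservable states: by_state_count scores higher
        m = matrix_from_rows("ABCD", ["0102", "1100", "0113", "1021"],
                             k=[2, 2, 4, 4])
        t = parse_newick(self.NEWICK)
        by = mk_loglik(t, m, MkModel(partition_mode="by_state_count",
                                     gamma_categories=0))
        single = mk_loglik(t, m, MkModel(partition_mode="single_matrix",
                                         gamma_categories=0))
        assert by > single

    def test_ascertainment_correction_raises_loglik(self):
        m = matrix_from_rows("ABCD", ["01", "10", "01", "11"])
        t = parse_newick(self.NEWICK)
        plain = mk_loglik(t, m, MkModel(gamma_categories=0))
        corrected = mk_loglik(t, m, MkModel(gamma_categories=0,
                                            ascertainment="variable_only"))
        assert corrected > plain    # dividing by P(variable) < 1


class TestMLSearch:
    def test_matches_exhaustive_topology_scan_at_six_taxa(self, asymtree6):
        model = MkModel(partition_mode="single_matrix", gamma_categories=0)
        for seed in (100, 102):
            m = assemble_matrix(asymtree6, SimulationConfig(n_chars=60, seed=seed))
            engine = MkPruningEngine(m, model)
            best = -np.inf
            for ut in enumerate_topologies(6):
                best = max(best, engine.optimize_branches(ut, None, sweeps=25))
            res = ml_search(m, model, MLSearchConfig(seed=0, n_starts=8))
            assert res.lnL >= best - 0.05

    def test_always_returns_binary_tree(self):
        gt = make_generating_tree(GeneratingTreeSpec("asymmetric", 8, 1.0))
        for seed in (0, 1):
            m = assemble_matrix(gt, SimulationConfig(n_chars=40, seed=seed))
            res = ml_search(m, MkModel(partition_mode="single_matrix"),
                            MLSearchConfig(seed=seed))
            assert resolution(res.tree) == 8 - 2

    def test_zero_homoplasy_recovers_generating_quartet(self):
        m = matrix_from_rows("ABCD", ["0" * 20, "0" * 20, "1" * 20, "1" * 20])
        res = ml_search(m, MkModel(gamma_categories=0), MLSearchConfig(seed=0))
        assert rf_distance(res.tree, parse_newick("((A,B),(C,D));")) == 0

    def test_gamma_shape_recovery_on_true_tree(self, symtree32):
        """Median relative error of the 4-category discrete-gamma shape
        estimate, on data simulated with a continuous-gamma shape."""
        from mkphylo.mk import _optimize_alpha
        from mkphylo._topo import UTree

        true_alpha = 0.75
        rng = np.random.default_rng(12)
        errs = []
        for _ in range(12):
            taxa, nucs = simulate_nucleotides(symtree32, 1000, 1.0, true_alpha,
                                              rng=rng)
            n_bin = 550
            data = np.empty_like(nucs)
            k = np.empty(1000, dtype=np.int8)
            for j in range(1000):
                if j < n_bin:
                    data[:, j] = recode_binary(nucs[:, j])
                    k[j] = 2
                else:
                    data[:, j] = recode_multistate(nucs[:, j])
                    k[j] = 4
            m = CharacterMatrix(taxa, data, k)
            engine = MkPruningEngine(m, MkModel(partition_mode="by_state_count"))
            ut = UTree.from_tree(symtree32, taxa)
            engine.optimize_branches(ut, 1.0, sweeps=3)
            alpha, _ = _optimize_alpha(engine, ut, 1.0, (0.02, 49.0))
            errs.append(abs(alpha - true_alpha) / true_alpha)
        assert np.median(errs) < 0.5


class TestBootstrapML:
    def test_clean_split_gets_full_support_and_bounds(self):
        base = np.array([[0, 0, 0, 1, 1, 1]] * 25).T.astype(np.int8)
        m = CharacterMatrix(list("ABCDEF"), base, np.full(25, 2, dtype=np.int8))
        model = MkModel(partition_mode="single_matrix", gamma_categories=0)
        tree = bootstrap_ml(m, model, reps=15,
                            config=MLSearchConfig(seed=0, slow_nni=False))
        sets = {frozenset({"D", "E", "F"}), frozenset({"A", "B", "C"})}
        from mkphylo.tree import _leafsets
        ls = _leafsets(tree)
        for n in tree.preorder():
            if n.is_leaf or n is tree.root or n.support is None:
                continue
            assert 0.0 <= n.support <= 1.0
            if frozenset(ls[n]) in sets:
                assert n.support == 1.0

    def test_signal_free_matrix_collapses_to_star(self):
        m = CharacterMatrix(list("ABCDEF"), np.zeros((6, 30), dtype=np.int8),
                            np.full(30, 2, dtype=np.int8))
        model = MkModel(partition_mode="single_matrix", gamma_categories=0)
        tree = bootstrap_ml(m, model, reps=10,
                            config=MLSearchConfig(seed=1, slow_nni=False))
        assert resolution(collapse_by_support(tree, 0.5)) == 1
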