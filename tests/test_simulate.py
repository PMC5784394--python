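"""Generating trees, HKY+Gamma simulation, recoding, matrix assembly
and homoplasy measurement/targeting."""

import math

import numpy as np
import pytest

from mkphylo.matrix import CharacterMatrix
from mkphylo.parsimony import fitch_lengths_per_character
from mkphylo.simulate import (GeneratingTreeSpec, HomoplasyTarget,
                              SimulationConfig, assemble_matrix,
                              ensemble_consistency_index,
                              hky_rate_matrix, hky_transition_matrices,
                              make_generating_tree, recode_binary,
                              recode_multistate,
                              sample_datasets_with_homoplasy_target,
                              simulate_nucleotides)
from mkphylo.tree import parse_newick, resolution

from conftest import matrix_from_rows

PI = (0.2, 0.2, 0.3, 0.3)


def _tip_depths(tree):
    out = []

    def rec(node, d):
        d += node.length or 0.0
        if node.is_leaf:
            out.append(d)
        for c in node.children:
            rec(c, d)

    rec(tree.root, 0.0)
    return out


def _cherries(tree):
    return sum(1 for n in tree.preorder()
               if len(n.children) == 2 and all(c.is_leaf for c in n.children))


class TestGeneratingTrees:
    def test_symmetric_fully_resolved_ultrametric(self, symtree32):
        assert resolution(symtree32) == 30
        assert np.allclose(_tip_depths(symtree32), 1.0)

    def test_asymmetric_is_an_ultrametric_caterpillar(self, asymtree32):
        assert resolution(asymtree32) == 30
        assert np.allclose(_tip_depths(asymtree32), 1.0)
        assert _cherries(asymtree32) == 1

    def test_symmetric_four_taxa_shape(self):
        t = make_generating_tree(GeneratingTreeSpec("symmetric", 4, 1.0))
        assert resolution(t) == 2

    def test_symmetric_requires_power_of_two(self):
        with pytest.raises(ValueError):
            make_generating_tree(GeneratingTreeSpec("symmetric", 12, 1.0))


class TestHKY:
    def test_transition_matrices_stochastic_and_reversible(self):
        pi = np.asarray(PI)
        Q = hky_rate_matrix(2.0, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        P = hky_transition_matrices(np.array([0.1, 1.0, 10.0]), 2.0, pi)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)

    def test_identity_at_zero_and_stationarity_at_infinity(self):
        P0 = hky_transition_matrices(np.array([0.0]), 2.0, PI)[0]
        assert np.allclose(P0, np.eye(4), atol=1e-12)
        Pinf = hky_transition_matrices(np.array([500.0]), 2.0, PI)[0]
        assert np.allclose(Pinf, np.tile(PI, (4, 1)), atol=1e-9)

    def test_kappa_one_uniform_pi_reduces_to_jukes_cantor(self):
        for t in (0.05, 0.37, 2.0):
            P = hky_transition_matrices(np.array([t]), 1.0, [0.25] * 4)[0]
            expect = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            assert abs(P[0, 0] - expect) < 1e-10

    def test_zero_branch_lengths_copy_root_state(self):
        t = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        _, nucs = simulate_nucleotides(t, 50, 1.0, 1.0, rng=np.random.default_rng(0))
        assert (nucs == nucs[0]).all()

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            simulate_nucleotides(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"),
                                 10, 1.0, 1.0, pi=[0.5, 0.5, 0.2, -0.2],
                                 rng=np.random.default_rng(0))


class TestRecoding:
    def test_purine_pyrimidine_definition(self):
        assert list(recode_binary(np.array(list("AGCT")))) == [0, 0, 1, 1]
        assert list(recode_binary(np.array(list("AAAA")))) == [0, 0, 0, 0]

    def test_multistate_fixed_bijection(self):
        assert list(recode_multistate(np.array(list("ACGT")))) == [0, 1, 2, 3]

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            recode_binary(np.array(list("ACGN")))

    def test_binary_recode_coarsens_multistate(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 4, 30)
        n_multi = len(np.unique(recode_multistate(col)))
        n_bin = len(np.unique(recode_binary(col)))
        assert n_multi >= n_bin

    def test_long_branch_binary_equilibrium_is_40_60(self):
        # R/Y recoding of the HKY stationary distribution [.2,.2,.3,.3]
        t = parse_newick("(A:0.001,B:50,C:50,D:50);")
        _, nucs = simulate_nucleotides(t, 40000, 1.0, 1e9, kappa=2.0, pi=PI,
                                       rng=np.random.default_rng(2))
        freq0 = (recode_binary(nucs[1]) == 0).mean()
        se = math.sqrt(0.4 * 0.6 / 40000)
        assert abs(freq0 - 0.4) < 3 * se


class TestAssembly:
    @pytest.mark.parametrize("n,nbin", [(100, 55), (350, 192), (1000, 550)])
    def test_binary_multistate_split(self, symtree32, n, nbin):
        m = assemble_matrix(symtree32, SimulationConfig(n_chars=n, seed=1))
        assert m.n_binary == nbin and m.n_multistate == n - nbin

    def test_same_seed_same_matrix(self, symtree32):
        cfg = SimulationConfig(n_chars=60, seed=99)
        a = assemble_matrix(symtree32, cfg)
        b = assemble_matrix(symtree32, cfg)
        assert np.array_equal(a.data, b.data)
        assert a.provenance == b.provenance

    def test_rate_and_shape_draws_have_unit_mean(self, symtree32):
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(n_chars=4)
        rs, alphas = [], []
        for _ in range(1000):
            m = assemble_matrix(symtree32, cfg, rng=rng)
            rs.append(m.provenance["r"])
            alphas.append(m.provenance["alpha"])
        for vals in (rs, alphas):     # Exponential(mean 1): sd = 1
            assert abs(np.mean(vals) - 1.0) < 3.0 / math.sqrt(1000)


class TestConsistencyIndex:
    def test_perfect_characters_give_ci_one(self):
        m = matrix_from_rows("ABCD", ["00", "00", "11", "11"])
        t = parse_newick("((A,B),(C,D));")
        assert ensemble_consistency_index(m, t) == 1.0

    def test_single_homoplastic_character(self):
        m = matrix_from_rows("ABCD", ["0", "1", "0", "1"])
        t = parse_newick("((A,B),(C,D));")
        # steps 2 (brute force over internal states), m = 1
        assert ensemble_consistency_index(m, t) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        taxa = list("ABCDEF")
        t = parse_newick("(((A,B),C),(D,(E,F)));")
        for _ in range(10):
            data = rng.integers(0, 3, (6, 12)).astype(np.int8)
            m = CharacterMatrix(taxa, data, np.full(12, 4, dtype=np.int8))
            s = fitch_lengths_per_character(t, m)
            mc = np.array([len(np.unique(data[:, j])) - 1 for j in range(12)])
            var = mc > 0
            expect = mc[var].sum() / s[var].sum()
            assert ensemble_consistency_index(m, t) == pytest.approx(expect)

    def test_all_invariant_is_undefined(self):
        m = matrix_from_rows("ABCD", ["00", "00", "00", "00"])
        with pytest.raises(ValueError):
            ensemble_consistency_index(m, parse_newick("((A,B),(C,D));"))


class TestHomoplasyTarget:
    def test_no_target_is_plain_assembly(self, symtree32):
        ens = sample_datasets_with_homoplasy_target(
            symtree32, SimulationConfig(n_chars=20, seed=5), 3)
        assert len(ens.matrices) == 3 and ens.attempts == 3

    def test_two_equal_bins_fill_exact_quotas(self, asymtree6):
        tgt = HomoplasyTarget([0.0, 0.7, 1.0], [0.5, 0.5])
        ens = sample_datasets_with_homoplasy_target(
            asymtree6, SimulationConfig(n_chars=30), 8, target=tgt,
            rng=np.random.default_rng(6))
        assert len(ens.matrices) == 8
        lo = sum(1 for ci in ens.ci_values if ci <= 0.7)
        assert lo == 4

    def test_high_ci_target_selects_low_rates(self, asymtree6):
        cfg = SimulationConfig(n_chars=30)
        high = sample_datasets_with_homoplasy_target(
            asymtree6, cfg, 6, target=HomoplasyTarget([0.9, 1.0], [1.0]),
            rng=np.random.default_rng(7))
        free = sample_datasets_with_homoplasy_target(
            asymtree6, cfg, 30, rng=np.random.default_rng(8))
        r_high = np.mean([m.provenance["r"] for m in high.matrices])
        r_free = np.mean([m.provenance["r"] for m in free.matrices])
        assert r_high < r_free

    def test_unfillable_bin_reports_range(self, asymtree6):
        tgt = HomoplasyTarget([0.0, 1e-6], [1.0])
        with pytest.raises(RuntimeError, match="achievable CI range"):
            sample_datasets_with_homoplasy_target(
                asymtree6, SimulationConfig(n_chars=30), 2, target=tgt,
                max_attempts_per_matrix=5, rng=np.random.default_rng(9))
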