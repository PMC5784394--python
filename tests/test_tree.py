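"""Tree structure, Newick I/O, bipartition algebra, consensus,
collapsing and resolution."""

import itertools

import dendropy
import numpy as np
import pytest

from mkphylo._topo import random_topology
from mkphylo.parsimony import enumerate_topologies
from mkphylo.simulate import GeneratingTreeSpec, make_generating_tree
from mkphylo.tree import (Bipartition, NewickError, Tree, TreeValidationError,
                          bipartitions, collapse_by_support,
                          majority_rule_consensus, parse_newick, resolution,
                          rf_distance, write_newick)


# ---------------------------------------------------------------- Newick

def test_parse_smallest_nontrivial_tree():
    t = parse_newick("((A:1,B:1):1,C:1);")
    assert t.taxa == {"A", "B", "C"}
    assert sum(1 for n in t.preorder() if not n.is_leaf) == 2


@pytest.mark.parametrize("text,expected", [
    ("((A,B)75,C,D);", [0.75]),
    ("((A,B)0.9,(C,D)0.4,E);", [0.9, 0.4]),
    ("((A,B)100,C,D);", [1.0]),
])
def test_support_autoscaling(text, expected):
    t = parse_newick(text)
    supports = [n.support for n in t.preorder()
                if not n.is_leaf and n.support is not None]
    assert supports == expected


def test_roundtrip_preserves_topology_lengths_support():
    text = "((A:0.1,B:0.25)0.9,(C:1,D:2)0.4,E:0.5);"
    t = parse_newick(text)
    t2 = parse_newick(write_newick(t))
    assert rf_distance(t, t2) == 0
    assert sorted(n.length for n in t2.preorder() if n.length is not None) == \
        sorted(n.length for n in t.preorder() if n.length is not None)
    assert sorted(n.support for n in t2.preorder() if n.support is not None) == \
        [0.4, 0.9]


def test_parse_errors_carry_offset():
    with pytest.raises(NewickError) as exc:
        parse_newick("((A,B),C")
    assert exc.value.offset >= 0
    with pytest.raises(NewickError):
        parse_newick("((A,B)!!;")
    with pytest.raises(TreeValidationError, match="duplicate"):
        parse_newick("((A,B),A);")


# ------------------------------------------------------------ bipartitions

def test_single_split_four_taxa():
    bips = bipartitions(parse_newick("((A,B),(C,D));"))
    assert bips == {Bipartition.from_leafset({"C", "D"}, {"A", "B", "C", "D"})}


def test_fully_resolved_32_taxon_tree_has_29_splits(symtree32):
    assert len(bipartitions(symtree32)) == 29


def test_star_and_tiny_trees_have_no_splits():
    assert bipartitions(parse_newick("(A,B,C,D,E,F);")) == set()
    assert bipartitions(parse_newick("((A,B),C);")) == set()


# ---------------------------------------------------------------- RF

def test_rf_identity_and_disjoint_quartets():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,C),(B,D));")
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2


def test_rf_taxon_mismatch_lists_difference():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,B),(C,E));")
    with pytest.raises(TreeValidationError, match="E"):
        rf_distance(t1, t2)


def test_rf_is_a_metric_on_all_five_taxon_topologies():
    taxa = list("ABCDE")
    trees = [ut.to_tree(taxa, with_lengths=False)
             for ut in enumerate_topologies(5)]
    assert len(trees) == 15
    d = [[rf_distance(a, b) for b in trees] for a in trees]
    for i, j, k in itertools.product(range(15), repeat=3):
        assert d[i][j] == d[j][i]
        assert d[i][j] >= 0
        assert (d[i][j] == 0) == (i == j)
        assert d[i][k] <= d[i][j] + d[j][k]


def _dendropy_rf(t1: Tree, t2: Tree) -> int:
    from dendropy.calculate import treecompare

    ns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                           taxon_namespace=ns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                           taxon_namespace=ns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return treecompare.symmetric_difference(d1, d2)


def test_rf_agrees_with_dendropy_on_random_pairs():
    rng = np.random.default_rng(42)
    for n in (8, 16, 32):
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(67):
            a = random_topology(n, rng).to_tree(taxa, with_lengths=False)
            b = random_topology(n, rng).to_tree(taxa, with_lengths=False)
            assert rf_distance(a, b) == _dendropy_rf(a, b)


def test_rf_pectinate_vs_balanced_matches_oracle():
    sym = make_generating_tree(GeneratingTreeSpec("symmetric", 32, 1.0))
    asym = make_generating_tree(GeneratingTreeSpec("asymmetric", 32, 1.0))
    d = rf_distance(sym, asym)
    assert d == _dendropy_rf(sym, asym)
    assert 0 < d <= 2 * (32 - 3)


# ---------------------------------------------------------------- consensus

def test_consensus_of_identical_trees_is_identity_with_full_support():
    t = parse_newick("((A,B),(C,D),(E,F));")
    cons = majority_rule_consensus([t, t, t])
    assert rf_distance(cons, t) == 0
    assert all(n.support == 1.0 for n in cons.preorder()
               if not n.is_leaf and n is not cons.root)


def test_consensus_two_thirds_majority():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,C),(B,D));")
    cons = majority_rule_consensus([t1, t1, t2])
    bips = bipartitions(cons)
    assert bips == {Bipartition.from_leafset({"C", "D"}, {"A", "B", "C", "D"})}
    sup = [n.support for n in cons.preorder()
           if not n.is_leaf and n.support is not None]
    assert sup == pytest.approx([2 / 3])


def test_consensus_of_maximally_different_trees_is_star():
    t1 = parse_newick("(((((A,B),C),D),E),F);")
    t2 = parse_newick("(((((C,F),A),E),B),D);")
    assert rf_distance(t1, t2) == 2 * (6 - 3)
    cons = majority_rule_consensus([t1, t2])
    assert resolution(cons) == 1


def test_consensus_threshold_is_strict():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,C),(B,D));")
    # each split at exactly 1/2: strictly-greater comparison drops both
    cons = majority_rule_consensus([t1, t2], threshold=0.5)
    assert bipartitions(cons) == set()
    with pytest.raises(TreeValidationError):
        majority_rule_consensus([])


# ---------------------------------------------------------------- collapse

def test_collapse_below_threshold():
    t = parse_newick("(((A,B)0.9,C)0.4,D,E);")
    out = collapse_by_support(t, 0.5)
    assert resolution(out) == resolution(t) - 1
    assert bipartitions(out) == {
        Bipartition.from_leafset({"A", "B"}, {"A", "B", "C", "D", "E"})}


def test_collapse_retains_exact_threshold_support():
    t = parse_newick("(((A,B)0.5,C)0.9,D,E);")
    out = collapse_by_support(t, 0.5)
    assert resolution(out) == resolution(t)


def test_collapse_identity_when_all_supported():
    t = parse_newick("(((A,B)0.8,C)0.7,D,E);")
    assert rf_distance(collapse_by_support(t, 0.5), t) == 0


def test_collapse_requires_support_everywhere():
    t = parse_newick("(((A,B)0.8,C),D,E);")
    with pytest.raises(TreeValidationError):
        collapse_by_support(t, 0.5)


def test_collapse_resolution_non_increasing_in_threshold():
    rng = np.random.default_rng(7)
    taxa = [f"t{i}" for i in range(12)]
    t = random_topology(12, rng).to_tree(taxa, with_lengths=False)
    for node in t.preorder():
        if not node.is_leaf and node is not t.root:
            node.support = float(rng.random())
    res = [resolution(collapse_by_support(t, x))
           for x in np.linspace(0, 1, 11)]
    assert res == sorted(res, reverse=True)


# ------------------------------------------------------- property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=40, derandomize=True, deadline=None)
@given(n=st.integers(5, 20), seed=st.integers(0, 10 ** 6))
def test_newick_roundtrip_and_split_count_on_random_trees(n, seed):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    t = random_topology(n, rng).to_tree(taxa)
    back = parse_newick(write_newick(t))
    assert rf_distance(t, back) == 0
    assert len(bipartitions(t)) == n - 3      # binary unrooted tree


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_consensus_splits_occur_in_majority_of_inputs(seed):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(8)]
    trees = [random_topology(8, rng).to_tree(taxa, with_lengths=False)
             for _ in range(5)]
    cons = majority_rule_consensus(trees)
    for bip in bipartitions(cons):
        count = sum(bip in bipartitions(t) for t in trees)
        assert count / len(trees) > 0.5


# ---------------------------------------------------------------- resolution

@pytest.mark.parametrize("newick,expected", [
    ("((A,B),(C,D),E);", 3),
    ("(A,B,C,D,E);", 1),
    ("((A,B),(C,D));", 2),
])
def test_resolution_examples(newick, expected):
    assert resolution(parse_newick(newick)) == expected


def test_resolution_extremes_32_taxa(symtree32):
    assert resolution(symtree32) == 30
    star = parse_newick("(" + ",".join(f"t{i}" for i in range(32)) + ");")
    assert resolution(star) == 1
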