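"""Equal-weights parsimony: Fitch/Hartigan scoring, heuristic search
retaining equally most-parsimonious trees, and nonparametric bootstrap.

Characters are unordered; state sets are held as bitmasks and all
characters are scored simultaneously with numpy over the compressed
site patterns.  Binary (fully resolved) trees use the classic Fitch
union/intersection recursion; multifurcating nodes are scored with
Hartigan's generalisation (per node, cost = number of children minus
the maximum state count over the children's preferred sets), which
reduces to Fitch on bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._topo import UTree
from .matrix import MISSING, CharacterMatrix
from .tree import (Tree, annotate_supports, bipartitions,
                   majority_rule_consensus)

__all__ = [
    "SearchConfig",
    "ParsimonyResult",
    "fitch_length",
    "mp_search",
    "bootstrap_parsimony",
    "enumerate_topologies",
]


@dataclass
class SearchConfig:
    n_random_addition_starts: int = 10
    moves: tuple[str, ...] = ("nni", "spr")
    mp_tree_cap: int = 500
    seed: Optional[int] = None
    exhaustive: bool = False
    plateau_max_evals: int = 4000
    bootstrap_starts: int = 3


@dataclass
class ParsimonyResult:
    best_score: int
    mp_trees: list[Tree]
    consensus: Tree
    cap_hit: bool = False


# ---------------------------------------------------------------------
# pattern packing and scoring
# ---------------------------------------------------------------------

def pack_patterns(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Compress characters into unique bitmask site patterns.

    Returns (masks, weights): masks has shape (n_taxa, n_patterns) with
    bit s set when state s is compatible with the observation (missing
    entries allow every state of the character's alphabet).
    """
    data = matrix.data
    k = matrix.k_per_char
    full = ((1 << k.astype(np.int32)) - 1).astype(np.uint8)
    masks = np.where(data == MISSING, full[None, :],
                     (1 << data.clip(min=0)).astype(np.uint8))
    patterns, counts = np.unique(masks.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(np.float64)


def _score_utree(ut: UTree, masks: np.ndarray, weights: np.ndarray) -> int:
    """Fitch length of a binary UTree over all patterns."""
    below: dict[int, np.ndarray] = {}
    P = masks.shape[1]
    steps = np.zeros(P, dtype=np.int32)
    for v in ut.topo_order():
        c1, c2 = ut.children[v]
        a = below[c1] if c1 in below else masks[c1]
        b = below[c2] if c2 in below else masks[c2]
        inter = a & b
        empty = inter == 0
        below[v] = np.where(empty, a | b, inter)
        steps += empty
    (c0,) = ut.children[ut.root]
    top = below[c0] if c0 in below else masks[c0]
    steps = steps + ((top & masks[ut.root]) == 0)
    return int(np.dot(steps, weights))


def fitch_lengths_per_character(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum state changes on ``tree`` (Hartigan scoring,
    valid for multifurcating trees)."""
    if tree.taxa != frozenset(matrix.taxa):
        raise ValueError("tree and matrix taxon sets differ")
    row = {name: i for i, name in enumerate(matrix.taxa)}
    data = matrix.data
    k = matrix.k_per_char
    full = ((1 << k.astype(np.int32)) - 1).astype(np.uint8)
    leaf_masks = np.where(data == MISSING, full[None, :],
                          (1 << data.clip(min=0)).astype(np.uint8))

    steps = np.zeros(matrix.n_chars, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = leaf_masks[row[node.name]]
            continue
        counts = np.zeros((4, matrix.n_chars), dtype=np.int16)
        for child in node.children:
            m = sets.pop(id(child))
            for s in range(4):
                counts[s] += (m >> s) & 1
        mx = counts.max(axis=0)
        steps += len(node.children) - mx
        chosen = np.zeros(matrix.n_chars, dtype=np.uint8)
        for s in range(4):
            chosen |= ((counts[s] == mx).astype(np.uint8) << s)
        sets[id(node)] = chosen
    return steps


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Total parsimony length: sum over characters of the minimum number
    of state changes; invariant characters contribute 0."""
    return int(fitch_lengths_per_character(tree, matrix).sum())


# ---------------------------------------------------------------------
# search
# ---------------------------------------------------------------------

def enumerate_topologies(n: int):
    """Yield every unrooted binary topology on leaves 0..n-1 (there are
    (2n-5)!! of them) by exhaustive stepwise addition."""
    base = UTree(n)
    base.start(0, 1)
    if n == 2:
        yield base
        return

    def expand(ut: UTree, leaf: int):
        if leaf == n:
            yield ut
            return
        for at in list(ut.edges()):
            child = ut.copy()
            child.insert_leaf(leaf, at)
            yield from expand(child, leaf + 1)

    yield from expand(base, 2)


def _stepwise_addition(order: Sequence[int], masks, weights,
                       rng: np.random.Generator) -> UTree:
    n = len(order)
    ut = UTree(masks.shape[0])
    ut.start(order[0], order[1])
    for leaf in order[2:]:
        best_edges, best = [], None
        for at in ut.edges():
            ut.insert_leaf(leaf, at)
            s = _score_utree(ut, masks, weights)
            ut.remove_leaf(leaf)
            if best is None or s < best:
                best, best_edges = s, [at]
            elif s == best:
                best_edges.append(at)
        ut.insert_leaf(leaf, best_edges[rng.integers(len(best_edges))])
    return ut


def _nni_hill_climb(ut: UTree, score: int, masks, weights) -> int:
    improved = True
    while improved:
        improved = False
        for v in ut.internal_edges():
            for which in (0, 1):
                ut.nni(v, which)
                s = _score_utree(ut, masks, weights)
                if s < score:
                    score = s
                    improved = True
                else:
                    ut.nni(v, which)
    return score


def _spr_sweep(ut: UTree, score: int, masks, weights) -> tuple[UTree, int, bool]:
    improved_any = False
    improved = True
    while improved:
        improved = False
        for v in list(ut.edges()):
            if ut.parent[v] == ut.root:
                continue
            for target in ut.spr_targets(v):
                cand = ut.copy()
                cand.spr(v, target)
                s = _score_utree(cand, masks, weights)
                if s < score:
                    ut, score = cand, s
                    improved = improved_any = True
                    break
            if improved:
                break
    return ut, score, improved_any


def mp_search(matrix: CharacterMatrix, config: Optional[SearchConfig] = None) -> ParsimonyResult:
    """Heuristic equal-weights parsimony search.

    Random-addition starts followed by NNI (and optionally SPR) hill
    climbing; all distinct topologies tying the best score are pooled
    (up to ``mp_tree_cap``), then the tie set is expanded over
    equal-score NNI neighbours so that the majority-rule consensus
    reflects the most-parsimonious plateau.
    """
    config = config or SearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("parsimony search requires at least 4 taxa")
    rng = np.random.default_rng(config.seed)
    masks, weights = pack_patterns(matrix)

    best: Optional[int] = None
    tied: dict[frozenset, UTree] = {}

    def record(ut: UTree, s: int) -> None:
        nonlocal best, tied
        if best is None or s < best:
            best, tied = s, {ut.split_key(): ut.copy()}
        elif s == best:
            tied.setdefault(ut.split_key(), ut.copy())

    if config.exhaustive:
        if matrix.n_taxa > 8:
            raise ValueError("exhaustive enumeration is limited to <= 8 taxa")
        for ut in enumerate_topologies(matrix.n_taxa):
            record(ut, _score_utree(ut, masks, weights))
    else:
        for _ in range(config.n_random_addition_starts):
            order = list(rng.permutation(matrix.n_taxa))
            ut = _stepwise_addition(order, masks, weights, rng)
            s = _score_utree(ut, masks, weights)
            while True:
                s = _nni_hill_climb(ut, s, masks, weights)
                if "spr" not in config.moves:
                    break
                ut, s, moved = _spr_sweep(ut, s, masks, weights)
                if not moved:
                    break
            record(ut, s)

    cap_hit = _expand_plateau(tied, best, masks, weights, config)
    taxa = matrix.taxa
    mp_trees = [ut.to_tree(taxa, with_lengths=False) for ut in tied.values()]
    consensus = (mp_trees[0] if len(mp_trees) == 1
                 else majority_rule_consensus(mp_trees))
    if len(mp_trees) == 1:
        consensus = consensus.copy()
        for node in consensus.preorder():
            if not node.is_leaf and node is not consensus.root:
                node.support = 1.0
    return ParsimonyResult(best, mp_trees, consensus, cap_hit)


def _expand_plateau(tied: dict, best: int, masks, weights,
                    config: SearchConfig) -> bool:
    """Breadth-first walk over equal-score NNI neighbours of the tied
    set, bounded by the tree cap and an evaluation budget."""
    if config.exhaustive:
        return False
    queue = list(tied.values())
    evals = 0
    cap_hit = False
    while queue and evals < config.plateau_max_evals:
        ut = queue.pop()
        for v in ut.internal_edges():
            for which in (0, 1):
                ut.nni(v, which)
                evals += 1
                s = _score_utree(ut, masks, weights)
                if s == best:
                    key = ut.split_key()
                    if key not in tied:
                        if len(tied) >= config.mp_tree_cap:
                            cap_hit = True
                        else:
                            cand = ut.copy()
                            tied[key] = cand
                            queue.append(cand)
                ut.nni(v, which)
                if evals >= config.plateau_max_evals or cap_hit:
                    return cap_hit
    return cap_hit


# ---------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------

def bootstrap_parsimony(matrix: CharacterMatrix, reps: int = 250,
                        config: Optional[SearchConfig] = None,
                        result: Optional[ParsimonyResult] = None) -> Tree:
    """Nonparametric bootstrap clade support for the parsimony consensus.

    Each replicate resamples characters with replacement (realised as a
    multinomial redraw of site-pattern weights), runs a reduced search
    (fewer starts, NNI only), and contributes its replicate consensus;
    the support of each split of the original MP consensus is the
    fraction of replicate trees containing it.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    if result is None:
        result = mp_search(matrix, config)
    masks, weights = pack_patterns(matrix)
    n_chars = matrix.n_chars
    probs = weights / weights.sum()
    taxa = matrix.taxa

    target_splits = bipartitions(result.consensus)
    hits = {bip: 0 for bip in target_splits}
    for _ in range(reps):
        w = rng.multinomial(n_chars, probs).astype(np.float64)
        rep_best: Optional[int] = None
        rep_tied: dict[frozenset, UTree] = {}
        for _ in range(config.bootstrap_starts):
            order = list(rng.permutation(matrix.n_taxa))
            ut = _stepwise_addition(order, masks, w, rng)
            s = _score_utree(ut, masks, w)
            s = _nni_hill_climb(ut, s, masks, w)
            if rep_best is None or s < rep_best:
                rep_best, rep_tied = s, {ut.split_key(): ut}
            elif s == rep_best:
                rep_tied.setdefault(ut.split_key(), ut)
        rep_trees = [u.to_tree(taxa, with_lengths=False) for u in rep_tied.values()]
        rep_cons = (rep_trees[0] if len(rep_trees) == 1
                    else majority_rule_consensus(rep_trees))
        rep_splits = bipartitions(rep_cons)
        for bip in target_splits:
            if bip in rep_splits:
                hits[bip] += 1

    annotated = result.consensus.copy()
    annotate_supports(annotated, {b: h / reps for b, h in hits.items()})
    return annotated
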