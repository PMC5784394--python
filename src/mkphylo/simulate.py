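"""Synthetic-data stage: generating trees, HKY+Gamma nucleotide
simulation, recoding to morphology-like categorical characters, and
homoplasy (ensemble consistency index) measurement and targeting.

The generating process deliberately violates the Mk model used for
inference: characters evolve as nucleotides under HKY (kappa = 2,
stationary distribution pi = [0.2, 0.2, 0.3, 0.3] on A, G, C, T) with
continuous gamma among-character rate variation, and are then recoded
either as purine/pyrimidine binary characters (stationary [0.4, 0.6])
or as 4-state characters (A->0, C->1, G->2, T->3).  Each dataset draws
an overall rate and a gamma shape independently from an exponential
distribution of mean 1.  The binary:multistate mix is 55:45.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .tree import Tree, TreeNode

__all__ = [
    "GeneratingTreeSpec",
    "SimulationConfig",
    "HomoplasyTarget",
    "HomoplasyEnsemble",
    "make_generating_tree",
    "hky_rate_matrix",
    "hky_transition_matrices",
    "simulate_nucleotides",
    "recode_binary",
    "recode_multistate",
    "assemble_matrix",
    "ensemble_consistency_index",
    "sample_datasets_with_homoplasy_target",
]

# internal nucleotide coding keeps purines first so that R/Y recoding is
# a simple threshold: (A, G, C, T) = (0, 1, 2, 3)
_NUC_ORDER = "AGCT"
_DEFAULT_PI = (0.2, 0.2, 0.3, 0.3)


@dataclass
class GeneratingTreeSpec:
    shape: str = "symmetric"          # {"symmetric", "asymmetric"}
    n_taxa: int = 32
    depth: float = 1.0                # root-to-tip path length, substitutions/char


@dataclass
class SimulationConfig:
    n_chars: int = 100
    kappa: float = 2.0
    pi: tuple[float, float, float, float] = _DEFAULT_PI   # (A, G, C, T)
    binary_fraction: float = 0.55
    rate_mean: float = 1.0            # dataset rate r ~ Exponential(mean 1)
    shape_mean: float = 1.0           # gamma shape alpha ~ Exponential(mean 1)
    seed: Optional[int] = None

    def validate(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be positive and sum to 1")
        if not 0 < self.binary_fraction < 1:
            raise ValueError("binary_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------
# generating trees
# ---------------------------------------------------------------------

def _taxon_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def make_generating_tree(spec: GeneratingTreeSpec) -> Tree:
    """Ultrametric generating tree: fully balanced ("symmetric") or
    pectinate/caterpillar ("asymmetric"), all tips contemporaneous at
    the given depth."""
    n, depth = spec.n_taxa, spec.depth
    if n < 4:
        raise ValueError("generating trees need at least 4 taxa")
    names = _taxon_names(n)
    if spec.shape == "symmetric":
        levels = int(np.log2(n))
        if 2 ** levels != n:
            raise ValueError("symmetric shape requires n_taxa to be a power of 2")
        step = depth / levels

        def build(lo: int, hi: int) -> TreeNode:
            if hi - lo == 1:
                return TreeNode(names[lo], length=step)
            node = TreeNode(length=step)
            mid = (lo + hi) // 2
            node.add_child(build(lo, mid))
            node.add_child(build(mid, hi))
            return node

        root = TreeNode()
        mid = n // 2
        root.add_child(build(0, mid))
        root.add_child(build(mid, n))
        root.children[0].length = step
        root.children[1].length = step
        return Tree(root)
    if spec.shape == "asymmetric":
        # speciation events evenly spaced in time; node j sits at age
        # depth * (1 - j/(n-1)), so every internode has length depth/(n-1)
        dt = depth / (n - 1)
        node = TreeNode()
        root = node
        for j in range(n - 2):
            age = depth - j * dt
            node.add_child(TreeNode(names[j], length=age))
            nxt = TreeNode(length=dt)
            node.add_child(nxt)
            node = nxt
        last_age = depth - (n - 2) * dt
        node.add_child(TreeNode(names[n - 2], length=last_age))
        node.add_child(TreeNode(names[n - 1], length=last_age))
        return Tree(root)
    raise ValueError(f"unknown tree shape {spec.shape!r}")


# ---------------------------------------------------------------------
# HKY simulation
# ---------------------------------------------------------------------

def hky_rate_matrix(kappa: float, pi: Sequence[float]) -> np.ndarray:
    """HKY instantaneous rate matrix on (A, G, C, T), normalised to one
    expected substitution per unit time at stationarity."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be positive and sum to 1")
    transition = np.zeros((4, 4), dtype=bool)
    transition[0, 1] = transition[1, 0] = True   # A <-> G
    transition[2, 3] = transition[3, 2] = True   # C <-> T
    Q = np.where(transition, kappa, 1.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def _hky_eigen(kappa: float, pi: np.ndarray):
    Q = hky_rate_matrix(kappa, pi)
    sq = np.sqrt(pi)
    S = Q * sq[:, None] / sq[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    A = V / sq[:, None]
    B = V.T * sq[None, :]
    return lam, A, B


def hky_transition_matrices(t: np.ndarray, kappa: float,
                            pi: Sequence[float]) -> np.ndarray:
    """Stack of HKY transition matrices P(t_m), shape (m, 4, 4)."""
    pi = np.asarray(pi, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("branch lengths must be non-negative")
    lam, A, B = _hky_eigen(kappa, pi)
    E = np.exp(lam[None, :] * t[:, None])
    P = np.einsum("ij,mj,jk->mik", A, E, B)
    return np.clip(P, 0.0, None)


def simulate_nucleotides(tree: Tree, n: int, r: float, alpha: float,
                         kappa: float = 2.0, pi: Sequence[float] = _DEFAULT_PI,
                         rng: Optional[np.random.Generator] = None,
                         seed: Optional[int] = None) -> tuple[list[str], np.ndarray]:
    """Simulate ``n`` independent nucleotide characters down ``tree``.

    Each character draws a continuous rate multiplier g ~ Gamma(shape
    alpha, mean 1); the effective length of a branch of length t for
    character c is t * r * g_c.  Returns (taxa, states) with states
    coded 0..3 on the internal (A, G, C, T) order.
    """
    if r <= 0 or alpha <= 0:
        raise ValueError("rate and gamma shape must be positive")
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be positive and sum to 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    lam, A, B = _hky_eigen(kappa, pi)
    g = rng.gamma(alpha, 1.0 / alpha, size=n)

    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(4, size=n, p=pi)
    taxa, rows = [], []
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            t = node.length if node.length is not None else 0.0
            t_eff = t * r * g
            parent_states = states[id(node.parent)]
            if t == 0.0:
                child_states = parent_states.copy()
            else:
                E = np.exp(lam[None, :] * t_eff[:, None])
                P = np.clip(np.einsum("ij,mj,jk->mik", A, E, B), 0.0, None)
                probs = P[np.arange(n), parent_states, :]
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random(n)
                child_states = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            states[id(node)] = child_states
        if node.is_leaf:
            taxa.append(node.name)
            rows.append(states[id(node)])
    return taxa, np.asarray(rows, dtype=np.int8)


# ---------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------

def _to_codes(column: np.ndarray) -> np.ndarray:
    col = np.asarray(column)
    if col.dtype.kind in ("U", "S", "O"):
        lut = {c: i for i, c in enumerate(_NUC_ORDER)}
        try:
            return np.asarray([lut[str(c).upper()] for c in col], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"not a plain nucleotide: {exc.args[0]!r}") from None
    col = col.astype(np.int8)
    if np.any((col < 0) | (col > 3)):
        raise ValueError("nucleotide codes must lie in 0..3")
    return col


def recode_binary(column: np.ndarray) -> np.ndarray:
    """R/Y recoding: purines (A, G) -> 0, pyrimidines (C, T) -> 1."""
    codes = _to_codes(column)
    return (codes >= 2).astype(np.int8)


def recode_multistate(column: np.ndarray) -> np.ndarray:
    """Fixed 4-state recoding A->0, C->1, G->2, T->3."""
    codes = _to_codes(column)
    lut = np.array([0, 2, 1, 3], dtype=np.int8)   # internal order is A,G,C,T
    return lut[codes]


# ---------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------

def assemble_matrix(tree: Tree, config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> CharacterMatrix:
    """Simulate one morphology-like matrix on ``tree``.

    A dataset-level rate r and gamma shape alpha are drawn once (each
    exponential with the configured means); round-half-even of
    binary_fraction * n_chars columns are R/Y-recoded binary characters
    and the remainder 4-state; column order is shuffled.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_chars
    r = rng.exponential(config.rate_mean)
    alpha = rng.exponential(config.shape_mean)
    taxa, nucs = simulate_nucleotides(tree, n, r, alpha, config.kappa,
                                      config.pi, rng=rng)
    # exact round-half-even (0.55 * 350 must give 192, not the float 192.5000…3)
    from fractions import Fraction

    n_bin = round(Fraction(str(config.binary_fraction)) * n)
    data = np.empty_like(nucs)
    k = np.empty(n, dtype=np.int8)
    for j in range(n):
        if j < n_bin:
            data[:, j] = recode_binary(nucs[:, j])
            k[j] = 2
        else:
            data[:, j] = recode_multistate(nucs[:, j])
            k[j] = 4
    perm = rng.permutation(n)
    return CharacterMatrix(taxa, data[:, perm], k[perm],
                           provenance={"r": float(r), "alpha": float(alpha),
                                       "seed": config.seed})


# ---------------------------------------------------------------------
# homoplasy
# ---------------------------------------------------------------------

def ensemble_consistency_index(matrix: CharacterMatrix, tree: Tree) -> float:
    """Ensemble consistency index CI = sum m_c / sum s_c over variable
    characters, with m_c = (observed states - 1) and s_c = parsimony
    steps on ``tree``.  CI = 1 means no homoplasy."""
    from .parsimony import fitch_lengths_per_character
    from .matrix import MISSING

    s = fitch_lengths_per_character(tree, matrix)
    m = np.array([
        max(len(np.unique(matrix.data[:, j][matrix.data[:, j] != MISSING])) - 1, 0)
        for j in range(matrix.n_chars)
    ])
    variable = m > 0
    if not variable.any():
        raise ValueError("consistency index undefined: all characters invariant")
    return float(m[variable].sum() / s[variable].sum())


@dataclass
class HomoplasyTarget:
    """Binned target distribution over ensemble CI: matrices are accepted
    into bins (bin_edges[j], bin_edges[j+1]] until each bin's quota
    (proportions * n_matrices) is met."""
    bin_edges: Sequence[float]
    proportions: Sequence[float]

    def validate(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        props = np.asarray(self.proportions, dtype=float)
        if len(edges) != len(props) + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("need ascending bin_edges with len(proportions)+1 entries")
        if abs(props.sum() - 1.0) > 1e-8 or np.any(props < 0):
            raise ValueError("proportions must be non-negative and sum to 1")


@dataclass
class HomoplasyEnsemble:
    matrices: list[CharacterMatrix]
    ci_values: list[float]
    attempts: int


def _quotas(n: int, proportions: np.ndarray) -> np.ndarray:
    raw = proportions * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def sample_datasets_with_homoplasy_target(
        tree: Tree, config: SimulationConfig, n_matrices: int,
        target: Optional[HomoplasyTarget] = None,
        max_attempts_per_matrix: int = 200,
        rng: Optional[np.random.Generator] = None,
        search_config=None) -> HomoplasyEnsemble:
    """Rejection-sample matrices until the binned CI quotas are filled.

    Each attempt is a fresh :func:`assemble_matrix` draw (new r, alpha);
    its CI is measured on the matrix's own most-parsimonious tree (a
    quick parsimony search).  With target=None every draw is accepted.
    """
    from .parsimony import SearchConfig, mp_search

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if target is None:
        mats, cis = [], []
        for _ in range(n_matrices):
            m = assemble_matrix(tree, config, rng)
            mats.append(m)
        return HomoplasyEnsemble(mats, [], n_matrices)

    target.validate()
    edges = np.asarray(target.bin_edges, dtype=float)
    quotas = _quotas(n_matrices, np.asarray(target.proportions, dtype=float))
    filled = np.zeros_like(quotas)
    if search_config is None:
        search_config = SearchConfig(n_random_addition_starts=3, moves=("nni",),
                                     seed=int(rng.integers(2 ** 31)))
    mats, cis = [], []
    attempts = 0
    seen_ci: list[float] = []
    limit = n_matrices * max_attempts_per_matrix
    while filled.sum() < n_matrices:
        if attempts >= limit:
            lo = min(seen_ci) if seen_ci else float("nan")
            hi = max(seen_ci) if seen_ci else float("nan")
            raise RuntimeError(
                f"homoplasy target unfillable in {attempts} attempts; "
                f"achievable CI range observed: [{lo:.3f}, {hi:.3f}]"
            )
        attempts += 1
        m = assemble_matrix(tree, config, rng)
        try:
            mp = mp_search(m, search_config)
            ci = ensemble_consistency_index(m, mp.mp_trees[0])
        except ValueError:
            continue   # all-invariant matrix: no CI, reject
        seen_ci.append(ci)
        j = int(np.searchsorted(edges, ci, side="left")) - 1
        if j < 0 or j >= len(quotas):
            continue
        if filled[j] < quotas[j]:
            filled[j] += 1
            mats.append(m)
            cis.append(ci)
    return HomoplasyEnsemble(mats, cis, attempts)
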