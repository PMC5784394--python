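"""Maximum-likelihood inference under the Mk model.

The Mk model (Markov k-state) assigns equal rates to every transition
between the k states of a character and a uniform stationary
distribution, so its transition probabilities have the closed form

    p_same(t) = 1/k + (k-1)/k * exp(-k t / (k-1))
    p_diff(t) = 1/k -   1/k   * exp(-k t / (k-1))

Likelihoods are computed by Felsenstein pruning, vectorised over
compressed site patterns and discrete-gamma rate categories.  Under
``partition_mode="by_state_count"`` each character is scored with the
transition matrix of its declared state-space size (MrBayes-style);
``"single_matrix"`` scores every character with one k = max(k) matrix
(RAxML-style).  Optional ascertainment correction
(``"variable_only"``) conditions each character on being variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from ._topo import UTree, nj_topology, random_topology
from .matrix import MISSING, CharacterMatrix
from .tree import Tree, annotate_supports, bipartitions

__all__ = [
    "MkModel",
    "MLResult",
    "MLSearchConfig",
    "mk_transition_prob",
    "discrete_gamma_rates",
    "MkPruningEngine",
    "mk_loglik",
    "ml_search",
    "bootstrap_ml",
    "mismatch_distances",
]


@dataclass
class MkModel:
    partition_mode: str = "by_state_count"    # or "single_matrix"
    gamma_categories: int = 4                 # 0 switches rate variation off
    ascertainment: str = "none"               # or "variable_only"

    def validate(self) -> None:
        if self.partition_mode not in ("by_state_count", "single_matrix"):
            raise ValueError(f"unknown partition_mode {self.partition_mode!r}")
        if self.ascertainment not in ("none", "variable_only"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")
        if self.gamma_categories == 1 or self.gamma_categories < 0:
            raise ValueError("gamma_categories must be 0 (off) or >= 2")


def mk_transition_prob(k: int, t: float) -> np.ndarray:
    """k x k Mk transition probability matrix for branch length t."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if k < 2:
        raise ValueError("k must be >= 2")
    e = math.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-per-category discretisation of a mean-1 gamma distribution
    into ``ncat`` equal-probability rate categories."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat < 2:
        return np.ones(max(ncat, 1))
    edges = gammaincinv(alpha, np.arange(1, ncat) / ncat)
    upper = gammainc(alpha + 1, edges)
    cum = np.concatenate(([0.0], upper, [1.0]))
    return ncat * np.diff(cum)


# ---------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------

@dataclass
class _Partition:
    k: int
    tips: np.ndarray       # (n_leaves, P, k) tip partial likelihoods
    weights: np.ndarray    # (P,) pattern multiplicities
    char_idx: np.ndarray   # original column indices


class ZeroLikelihoodError(ValueError):
    pass


def _edge_message(D: np.ndarray, k: int, b: float, rates: np.ndarray) -> np.ndarray:
    """Propagate a conditional-likelihood array through an Mk edge of
    length b, per rate category.  Uses P_ij D_j = p_diff * sum(D) +
    (p_same - p_diff) * D_i with p_same - p_diff = exp(-k b r/(k-1))."""
    e = np.exp(-(k / (k - 1)) * b * rates)          # (R,)
    pd = (1.0 - e) / k
    S = D.sum(axis=-1, keepdims=True)
    return pd[None, :, None] * S + e[None, :, None] * D


class MkPruningEngine:
    """Vectorised pruning likelihood for one character matrix.

    Built once per matrix; ``loglik`` evaluates any binary tree over
    the same taxa.  Per-partition pattern weights can be overridden,
    which is how bootstrap pseudo-replicates are scored without
    repacking the data.
    """

    def __init__(self, matrix: CharacterMatrix, model: Optional[MkModel] = None):
        self.model = model or MkModel()
        self.model.validate()
        self.taxa = list(matrix.taxa)
        self.n_leaves = matrix.n_taxa
        self.n_chars = matrix.n_chars
        kvec = matrix.k_per_char.astype(int)
        if self.model.partition_mode == "single_matrix":
            kvec = np.full(matrix.n_chars, int(kvec.max()), dtype=int)
        self.partitions: list[_Partition] = []
        for k in sorted(set(kvec.tolist())):
            idx = np.where(kvec == k)[0]
            cols = matrix.data[:, idx]
            if np.any((cols >= k) & (cols != MISSING)):
                raise ValueError("observed state outside the declared state space")
            pats, counts = np.unique(cols.T, axis=0, return_counts=True)
            pats = pats.T                       # (n_leaves, P)
            P = pats.shape[1]
            tips = np.zeros((self.n_leaves, P, k))
            obs_i, obs_p = np.nonzero(pats != MISSING)
            tips[obs_i, obs_p, pats[obs_i, obs_p]] = 1.0
            mis_i, mis_p = np.nonzero(pats == MISSING)
            tips[mis_i, mis_p, :] = 1.0
            self.partitions.append(
                _Partition(k, tips, counts.astype(float), idx))

    # -- rates ---------------------------------------------------------
    def _rates(self, alpha: Optional[float]) -> np.ndarray:
        ncat = self.model.gamma_categories
        if ncat == 0:
            return np.ones(1)
        if alpha is None:
            raise ValueError("gamma is on: an alpha value is required")
        return discrete_gamma_rates(alpha, ncat)

    # -- full evaluation ----------------------------------------------
    def _partition_site_logliks(self, part: _Partition, ut: UTree,
                                rates: np.ndarray) -> np.ndarray:
        k = part.k
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        P = part.tips.shape[1]
        for v in ut.topo_order():
            acc = None
            sc = np.zeros(P)
            for c in ut.children[v]:
                if c in partial:
                    D, Dsc = partial[c], scale[c]
                else:
                    D, Dsc = part.tips[c][:, None, :], None
                msg = _edge_message(D, k, ut.blen[c], rates)
                acc = msg if acc is None else acc * msg
                if Dsc is not None:
                    sc += Dsc
            mx = acc.max(axis=(1, 2))
            if np.any(mx <= 0.0) or not np.all(np.isfinite(mx)):
                raise ZeroLikelihoodError("site likelihood underflowed to zero")
            partial[v] = acc / mx[:, None, None]
            scale[v] = sc + np.log(mx)
        (c0,) = ut.children[ut.root]
        D = partial[c0] if c0 in partial else part.tips[c0][:, None, :]
        sc = scale.get(c0, np.zeros(P))
        msg = _edge_message(D, k, ut.blen[c0], rates)
        site = (part.tips[ut.root][:, None, :] * msg).sum(axis=-1)   # (P, R)
        L = site.mean(axis=1) / k
        if np.any(L <= 0.0):
            raise ZeroLikelihoodError("site likelihood underflowed to zero")
        return np.log(L) + sc

    def _p_invariant(self, part: _Partition, ut: UTree, rates: np.ndarray) -> float:
        const = _Partition(
            k=part.k,
            tips=np.tile(np.eye(part.k)[None, :, :], (self.n_leaves, 1, 1)),
            weights=np.ones(part.k),
            char_idx=np.arange(part.k),
        )
        return float(np.exp(self._partition_site_logliks(const, ut, rates)).sum())

    def loglik(self, ut: UTree, alpha: Optional[float] = None,
               weights_override: Optional[list[np.ndarray]] = None) -> float:
        rates = self._rates(alpha)
        total = 0.0
        for i, part in enumerate(self.partitions):
            w = part.weights if weights_override is None else weights_override[i]
            if w.sum() == 0:
                continue
            ll = self._partition_site_logliks(part, ut, rates)
            total += float(np.dot(w, ll))
            if self.model.ascertainment == "variable_only":
                p_inv = self._p_invariant(part, ut, rates)
                total -= float(w.sum()) * math.log1p(-p_inv)
        return total

    # -- branch-length optimisation -----------------------------------
    def _updown(self, part: _Partition, ut: UTree, rates: np.ndarray):
        """Down (subtree) and up (rest-of-tree) conditionals for every
        edge, enabling O(patterns) per-branch likelihood evaluation."""
        k = part.k
        P = part.tips.shape[1]
        D: dict[int, np.ndarray] = {}
        Dsc: dict[int, np.ndarray] = {}
        order = ut.topo_order()
        for v in order:
            acc = None
            sc = np.zeros(P)
            for c in ut.children[v]:
                child = D[c] if c in D else part.tips[c][:, None, :]
                msg = _edge_message(child, k, ut.blen[c], rates)
                acc = msg if acc is None else acc * msg
                if c in Dsc:
                    sc += Dsc[c]
            mx = acc.max(axis=(1, 2))
            if np.any(mx <= 0.0):
                raise ZeroLikelihoodError("site likelihood underflowed to zero")
            D[v] = acc / mx[:, None, None]
            Dsc[v] = sc + np.log(mx)

        U: dict[int, np.ndarray] = {}
        Usc: dict[int, np.ndarray] = {}
        (c0,) = ut.children[ut.root]
        U[c0] = part.tips[ut.root][:, None, :] * np.ones((1, len(rates), 1))
        Usc[c0] = np.zeros(P)
        for v in reversed(order):               # parents before children
            if len(ut.children[v]) != 2:
                continue
            a, b = ut.children[v]
            up_msg = _edge_message(U[v], k, ut.blen[v], rates)
            for c, s in ((a, b), (b, a)):
                sib = D[s] if s in D else part.tips[s][:, None, :]
                sib_msg = _edge_message(sib, k, ut.blen[s], rates)
                acc = up_msg * sib_msg
                mx = acc.max(axis=(1, 2))
                if np.any(mx <= 0.0):
                    raise ZeroLikelihoodError("site likelihood underflowed to zero")
                U[c] = acc / mx[:, None, None]
                Usc[c] = Usc[v] + Dsc.get(s, 0.0) + np.log(mx)
        return D, Dsc, U, Usc

    def branch_profiles(self, ut: UTree, alpha: Optional[float]):
        """Per-edge sufficient statistics (s1, sU*sD, scale) per
        partition, for fast single-branch likelihood evaluation."""
        rates = self._rates(alpha)
        profiles: dict[int, list[tuple[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray]]] = {}
        for part in self.partitions:
            D, Dsc, U, Usc = self._updown(part, ut, rates)
            for v in ut.edges():
                Dv = D[v] if v in D else part.tips[v][:, None, :]
                dsc = Dsc.get(v, 0.0)
                s1 = (U[v] * Dv).sum(axis=-1)                     # (P, R)
                s00 = U[v].sum(axis=-1) * Dv.sum(axis=-1)         # (P, R)
                sc = Usc[v] + dsc
                profiles.setdefault(v, []).append((part.k, part.weights, s1, s00, sc))
        return profiles, rates

    def edge_loglik(self, profile, t: float, rates: np.ndarray) -> float:
        total = 0.0
        for k, w, s1, s00, sc in profile:
            e = np.exp(-(k / (k - 1)) * t * rates)
            pd = (1.0 - e) / k
            site = pd[None, :] * s00 + e[None, :] * s1            # (P, R)
            L = site.mean(axis=1) / k
            if np.any(L <= 0.0):
                return -np.inf
            total += float(np.dot(w, np.log(L) + sc))
        return total

    def optimize_branches(self, ut: UTree, alpha: Optional[float],
                          sweeps: int = 2, min_blen: float = 1e-8,
                          max_blen: float = 50.0, tol: float = 1e-6) -> float:
        """Coordinate-wise branch-length optimisation.  Each sweep
        computes up/down conditionals once and optimises every branch
        against them; a sweep that fails to improve the exact
        log-likelihood is rolled back."""
        best = self.loglik(ut, alpha)
        for _ in range(sweeps):
            old = np.array(ut.blen)
            profiles, rates = self.branch_profiles(ut, alpha)
            for v, profile in profiles.items():
                res = minimize_scalar(
                    lambda t: -self.edge_loglik(profile, t, rates),
                    bounds=(min_blen, max_blen), method="bounded",
                    options={"xatol": tol})
                ut.blen[v] = float(res.x)
            # all branches moved against the same (now stale) partials:
            # damp the joint step until the exact likelihood improves
            proposed = np.array(ut.blen)
            accepted = None
            for damp in (1.0, 0.5, 0.25, 0.125, 0.0625):
                trial = old + damp * (proposed - old)
                ut.blen[:] = [float(x) for x in trial]
                cand = self.loglik(ut, alpha)
                if cand > best:
                    accepted = cand
                    break
            if accepted is None:
                ut.blen[:] = [float(x) for x in old]
                break
            improved = accepted - best
            best = accepted
            if improved < 1e-4:
                break
        return best


class CachedPruning:
    """Incremental likelihood evaluation for MCMC.

    Caches per-node conditional likelihoods; a proposal supplies the
    set of nodes whose subtree changed (typically the path from the
    perturbed edge to the root) and only those partials are recomputed.
    The overlay is merged on acceptance and discarded on rejection.
    """

    def __init__(self, engine: MkPruningEngine, ut: UTree,
                 alpha: Optional[float]):
        self.engine = engine
        self.ut = ut
        self.alpha = alpha
        self.rates = engine._rates(alpha)
        # per partition: node -> (partial, scale)
        self.cache: list[dict[int, tuple[np.ndarray, np.ndarray]]] = [
            {} for _ in engine.partitions]
        self.lnl = self._evaluate(None, self.cache, self.rates)

    def _node_partial(self, part: _Partition, v: int,
                      store: dict, overlay: Optional[dict],
                      rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ut = self.ut
        k = part.k
        P = part.tips.shape[1]
        acc = None
        sc = np.zeros(P)
        for c in ut.children[v]:
            if overlay is not None and c in overlay:
                D, Dsc = overlay[c]
            elif c in store:
                D, Dsc = store[c]
            else:
                D, Dsc = part.tips[c][:, None, :], None
            msg = _edge_message(D, k, ut.blen[c], rates)
            acc = msg if acc is None else acc * msg
            if Dsc is not None:
                sc = sc + Dsc
        mx = acc.max(axis=(1, 2))
        if np.any(mx <= 0.0) or not np.all(np.isfinite(mx)):
            raise ZeroLikelihoodError("site likelihood underflowed to zero")
        return acc / mx[:, None, None], sc + np.log(mx)

    def _evaluate(self, dirty: Optional[set], caches: list,
                  rates: np.ndarray,
                  overlays: Optional[list] = None) -> float:
        ut = self.ut
        order = ut.topo_order()
        total = 0.0
        for i, part in enumerate(self.engine.partitions):
            store = caches[i]
            overlay = overlays[i] if overlays is not None else None
            for v in order:
                if dirty is None:
                    store[v] = self._node_partial(part, v, store, None, rates)
                elif v in dirty:
                    overlay[v] = self._node_partial(part, v, store, overlay, rates)
            (c0,) = ut.children[ut.root]
            if overlay is not None and c0 in overlay:
                D, sc = overlay[c0]
            elif c0 in store:
                D, sc = store[c0]
            else:
                D, sc = part.tips[c0][:, None, :], np.zeros(part.tips.shape[1])
            msg = _edge_message(D, part.k, ut.blen[c0], rates)
            site = (part.tips[ut.root][:, None, :] * msg).sum(axis=-1)
            L = site.mean(axis=1) / part.k
            if np.any(L <= 0.0):
                raise ZeroLikelihoodError("site likelihood underflowed to zero")
            w = part.weights
            total += float(np.dot(w, np.log(L) + sc))
            if self.engine.model.ascertainment == "variable_only":
                p_inv = self.engine._p_invariant(part, ut, rates)
                total -= float(w.sum()) * math.log1p(-p_inv)
        return total

    def propose(self, dirty: Optional[set]) -> tuple[float, Optional[list]]:
        """Evaluate the current (already mutated) tree.  ``dirty=None``
        forces a full re-evaluation (e.g. after an alpha change)."""
        if dirty is None:
            caches = [{} for _ in self.engine.partitions]
            lnl = self._evaluate(None, caches, self.rates)
            return lnl, caches
        overlays = [{} for _ in self.engine.partitions]
        lnl = self._evaluate(dirty, self.cache, self.rates, overlays)
        return lnl, overlays

    def propose_alpha(self, alpha: Optional[float]) -> tuple[float, list]:
        """Full re-evaluation under a new gamma shape."""
        rates = self.engine._rates(alpha)
        caches = [{} for _ in self.engine.partitions]
        lnl = self._evaluate(None, caches, rates)
        return lnl, caches

    def accept(self, lnl: float, payload: Optional[list],
               full: bool = False) -> None:
        if full:
            self.cache = payload
        elif payload is not None:
            for store, overlay in zip(self.cache, payload):
                store.update(overlay)
        self.lnl = lnl

    def set_alpha(self, alpha: Optional[float]) -> None:
        self.alpha = alpha
        self.rates = self.engine._rates(alpha)


def mk_loglik(tree: Tree, matrix: CharacterMatrix,
              model: Optional[MkModel] = None,
              alpha: Optional[float] = None) -> float:
    """Log-likelihood of ``matrix`` on ``tree`` (binary, with branch
    lengths) under the Mk model, by Felsenstein pruning with a uniform
    1/k root distribution."""
    model = model or MkModel()
    if model.gamma_categories > 0 and alpha is None:
        alpha = 1.0
    ut = UTree.from_tree(tree, list(matrix.taxa))
    return MkPruningEngine(matrix, model).loglik(ut, alpha)


# ---------------------------------------------------------------------
# search
# ---------------------------------------------------------------------

@dataclass
class MLSearchConfig:
    start: str = "nj"                 # or "random"
    n_starts: int = 1                 # first start NJ (unless "random"), rest random
    seed: Optional[int] = None
    max_rounds: int = 12
    branch_sweeps: int = 3
    branch_tol: float = 1e-6
    min_blen: float = 1e-8
    max_blen: float = 50.0
    alpha_bounds: tuple[float, float] = (0.02, 49.0)
    nni_tol: float = 1e-6
    slow_nni: bool = True
    bootstrap_sweeps: int = 1
    bootstrap_max_rounds: int = 5


@dataclass
class MLResult:
    tree: Tree
    lnL: float
    model: MkModel
    alpha: Optional[float] = None


def mismatch_distances(matrix: CharacterMatrix) -> np.ndarray:
    """Pairwise proportion of characters at which two taxa differ
    (characters with missing entries in either taxon are skipped)."""
    data = matrix.data
    obs = data != MISSING
    both = obs[:, None, :] & obs[None, :, :]
    diff = (data[:, None, :] != data[None, :, :]) & both
    denom = both.sum(axis=2).clip(min=1)
    return diff.sum(axis=2) / denom


def _optimize_alpha(engine: MkPruningEngine, ut: UTree, alpha: float,
                    bounds: tuple[float, float]) -> tuple[float, float]:
    res = minimize_scalar(
        lambda la: -engine.loglik(ut, math.exp(la)),
        bounds=(math.log(bounds[0]), math.log(bounds[1])), method="bounded",
        options={"xatol": 1e-3})
    best_alpha = math.exp(res.x)
    best = -res.fun
    base = engine.loglik(ut, alpha)
    if base >= best:
        return alpha, base
    return best_alpha, best


def ml_search(matrix: CharacterMatrix, model: Optional[MkModel] = None,
              config: Optional[MLSearchConfig] = None) -> MLResult:
    """Maximum-likelihood Mk tree search.

    Starts from a neighbour-joining topology on character mismatch
    distances (or a random-addition topology), then alternates gamma
    shape estimation, per-branch scalar optimisation and NNI sweeps
    until no interchange improves the likelihood.  Always returns a
    strictly binary tree (resolution n - 2).
    """
    model = model or MkModel(partition_mode="single_matrix")
    config = config or MLSearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("ML search requires at least 4 taxa")
    engine = MkPruningEngine(matrix, model)
    rng = np.random.default_rng(config.seed)
    best_result: Optional[MLResult] = None
    for s in range(max(config.n_starts, 1)):
        if config.start == "random" or s > 0:
            ut = random_topology(matrix.n_taxa, rng)
        else:
            ut = nj_topology(mismatch_distances(matrix), config.min_blen)
        for v in ut.edges():
            ut.blen[v] = min(max(ut.blen[v], config.min_blen), config.max_blen)
        result = _hill_climb(engine, ut, model, config)
        if best_result is None or result.lnL > best_result.lnL:
            best_result = result
    return best_result


def _hill_climb(engine: MkPruningEngine, ut: UTree, model: MkModel,
                config: MLSearchConfig) -> MLResult:
    alpha: Optional[float] = 1.0 if model.gamma_categories else None
    lnL = engine.loglik(ut, alpha)
    for _ in range(config.max_rounds):
        if model.gamma_categories:
            alpha, lnL = _optimize_alpha(engine, ut, alpha, config.alpha_bounds)
        lnL = engine.optimize_branches(ut, alpha, sweeps=config.branch_sweeps,
                                       min_blen=config.min_blen,
                                       max_blen=config.max_blen,
                                       tol=config.branch_tol)
        # fast pass: interchanges evaluated at current branch lengths
        improved = False
        for v in ut.internal_edges():
            for which in (0, 1):
                ut.nni(v, which)
                cand = engine.loglik(ut, alpha)
                if cand > lnL + config.nni_tol:
                    lnL = cand
                    improved = True
                else:
                    ut.nni(v, which)
        if improved:
            continue
        if not config.slow_nni:
            break
        # slow pass: re-optimise branch lengths for each candidate, to
        # escape optima that need a joint topology + length change
        for v in ut.internal_edges():
            for which in (0, 1):
                cand_ut = ut.copy()
                cand_ut.nni(v, which)
                cand = engine.optimize_branches(
                    cand_ut, alpha, sweeps=1, min_blen=config.min_blen,
                    max_blen=config.max_blen, tol=config.branch_tol)
                if cand > lnL + config.nni_tol:
                    ut, lnL = cand_ut, cand
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return MLResult(ut.to_tree(engine.taxa), lnL, model, alpha)


def bootstrap_ml(matrix: CharacterMatrix, model: Optional[MkModel] = None,
                 reps: int = 250, config: Optional[MLSearchConfig] = None,
                 result: Optional[MLResult] = None) -> Tree:
    """Nonparametric bootstrap support for the ML point-estimate tree.

    Pattern weights are redrawn multinomially per replicate (equivalent
    to resampling characters with replacement); each replicate runs a
    reduced search (NJ start, fewer sweeps, gamma shape frozen at the
    point estimate) and support is the fraction of replicate trees
    containing each split of the point estimate."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    model = model or MkModel(partition_mode="single_matrix")
    config = config or MLSearchConfig()
    if result is None:
        result = ml_search(matrix, model, config)
    engine = MkPruningEngine(matrix, model)
    rng = np.random.default_rng(config.seed)

    all_w = np.concatenate([p.weights for p in engine.partitions])
    probs = all_w / all_w.sum()
    split_at = np.cumsum([len(p.weights) for p in engine.partitions])[:-1]
    alpha = result.alpha

    # per-pattern mismatch indicators let each replicate rebuild its own
    # NJ starting tree from the resampled weights (decorrelates starts)
    n = matrix.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pat_cols = np.concatenate(
        [np.transpose(p.tips.argmax(axis=2) * (p.tips.sum(axis=2) == 1)
                      + (-1) * (p.tips.sum(axis=2) != 1)) for p in engine.partitions],
        axis=0)                                   # (P_total, n_leaves)
    both = (pat_cols[:, :, None] != -1) & (pat_cols[:, None, :] != -1)
    diff = (pat_cols[:, :, None] != pat_cols[:, None, :]) & both

    target = bipartitions(result.tree)
    hits = {b: 0 for b in target}
    for _ in range(reps):
        w = rng.multinomial(matrix.n_chars, probs).astype(float)
        for part, w_part in zip(engine.partitions, np.split(w, split_at)):
            part.weights = w_part
        denom = np.einsum("p,pij->ij", w, both).clip(min=1.0)
        dist = np.einsum("p,pij->ij", w, diff) / denom
        # infinitesimal symmetric jitter breaks NJ ties (flat-likelihood
        # data would otherwise give every replicate the same start tree)
        jit = rng.random((n, n)) * 1e-9
        dist = dist + jit + jit.T
        ut = nj_topology(dist, config.min_blen)
        lnL = engine.optimize_branches(ut, alpha, sweeps=config.bootstrap_sweeps,
                                       min_blen=config.min_blen,
                                       max_blen=config.max_blen,
                                       tol=config.branch_tol)
        for _ in range(config.bootstrap_max_rounds):
            improved = False
            for v in ut.internal_edges():
                for which in (0, 1):
                    ut.nni(v, which)
                    cand = engine.loglik(ut, alpha)
                    if cand > lnL + config.nni_tol:
                        lnL = cand
                        improved = True
                    else:
                        ut.nni(v, which)
            if not improved:
                break
        rep_splits = bipartitions(ut.to_tree(engine.taxa, with_lengths=False))
        for b in target:
            if b in rep_splits:
                hits[b] += 1

    annotated = result.tree.copy()
    annotate_supports(annotated, {b: h / reps for b, h in hits.items()})
    return annotated
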