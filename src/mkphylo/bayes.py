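"""Bayesian inference under the Mk model by Metropolis-Hastings MCMC.

The sampler moves over resolved topologies (uniform prior), branch
lengths (i.i.d. exponential prior) and, when gamma rate variation is
on, the gamma shape (exponential mean-1 prior).  Moves: NNI, SPR (with
merge/split branch-length bookkeeping and the corresponding Jacobian),
a branch-length multiplier, and a reflecting sliding window on the
gamma shape.  The point summary is the 50% majority-rule consensus of
the post-burnin topology sample, whose node annotations are posterior
probabilities (split frequencies) — by construction that consensus is
unchanged by collapsing nodes below 0.5 support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._topo import UTree, nj_topology, random_topology
from .matrix import CharacterMatrix
from .mk import CachedPruning, MkModel, MkPruningEngine, mismatch_distances
from .tree import Bipartition, Tree, bipartitions, majority_rule_consensus

__all__ = [
    "McmcConfig",
    "ChainSample",
    "PosteriorSample",
    "ConvergenceReport",
    "mcmc_run",
    "posterior_consensus",
    "convergence_diagnostics",
]


@dataclass
class McmcConfig:
    generations: int = 500_000
    sample_every: int = 500
    burnin_fraction: float = 0.25
    branch_prior_rate: float = 10.0     # exponential prior, mean 0.1
    move_weights: dict = field(default_factory=lambda: {
        "nni": 3.0, "spr": 1.0, "blen": 4.0, "alpha": 1.0})
    seed: Optional[int] = None
    n_chains: int = 2
    start: str = "nj"                   # or "random"
    fix_branch_lengths: bool = False
    likelihood_off: bool = False
    blen_multiplier_lambda: float = 2.0 * math.log(1.6)
    alpha_window: float = 0.75
    init_branch_opt: bool = True    # one likelihood branch-length pass at start
    start_nni_jitter: int = 10      # random NNIs applied to the start trees of
                                    # chains after the first (overdispersion)

    def validate(self) -> None:
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.generations < self.sample_every:
            raise ValueError("generations must be >= sample_every")


@dataclass
class ChainSample:
    trees: list[Tree]
    alphas: list[float]
    lnls: list[float]
    acceptance: dict[str, float]
    split_freqs: dict[Bipartition, float]


@dataclass
class PosteriorSample:
    chains: list[ChainSample]
    taxa: list[str]

    @property
    def trees(self) -> list[Tree]:
        return [t for c in self.chains for t in c.trees]

    @property
    def alphas(self) -> list[float]:
        return [a for c in self.chains for a in c.alphas]


def _split_frequencies(trees: Sequence[Tree]) -> dict[Bipartition, float]:
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for b in bipartitions(t):
            counts[b] = counts.get(b, 0) + 1
    n = len(trees)
    return {b: c / n for b, c in counts.items()}


def _run_chain(matrix: CharacterMatrix, model: MkModel, config: McmcConfig,
               rng: np.random.Generator, start_tree: Optional[Tree],
               chain_index: int = 0) -> ChainSample:
    n = matrix.n_taxa
    taxa = list(matrix.taxa)
    use_lik = not config.likelihood_off and matrix.n_chars > 0
    engine = MkPruningEngine(matrix, model) if use_lik else None
    gamma_on = model.gamma_categories > 0

    if start_tree is not None:
        ut = UTree.from_tree(start_tree, taxa)
    elif config.start == "nj" and use_lik:
        ut = nj_topology(mismatch_distances(matrix))
        if chain_index > 0:        # overdispersed starts for later chains
            for _ in range(config.start_nni_jitter):
                cands = ut.internal_edges()
                ut.nni(cands[rng.integers(len(cands))], int(rng.integers(2)))
    else:
        ut = random_topology(n, rng)
    lam = config.branch_prior_rate
    if not config.fix_branch_lengths and start_tree is None:
        for v in ut.edges():
            ut.blen[v] = rng.exponential(1.0 / lam)

    alpha = 1.0
    if use_lik and not config.fix_branch_lengths and config.init_branch_opt:
        engine.optimize_branches(ut, alpha if gamma_on else None, sweeps=2)
    cached = (CachedPruning(engine, ut, alpha if gamma_on else None)
              if use_lik else None)
    lnl = cached.lnl if use_lik else 0.0

    def log_prior(u: UTree, a: float) -> float:
        lp = sum(math.log(lam) - lam * u.blen[v] for v in u.edges())
        if gamma_on:
            lp += -a     # Exponential(1) on the gamma shape, up to a constant
        return lp

    def ancestors(u: int) -> set[int]:
        out: set[int] = set()
        while u != ut.root:
            out.add(u)
            u = ut.parent[u]
        return out

    lpr = log_prior(ut, alpha)

    moves, weights = [], []
    for name, w in config.move_weights.items():
        if name in ("blen", "spr") and config.fix_branch_lengths:
            continue
        if name == "alpha" and not gamma_on:
            continue
        if w > 0:
            moves.append(name)
            weights.append(float(w))
    weights = np.asarray(weights) / sum(weights)

    proposed = {m: 0 for m in moves}
    accepted = {m: 0 for m in moves}

    total_samples = config.generations // config.sample_every
    keep = int(math.floor(config.generations * (1 - config.burnin_fraction)
                          / config.sample_every))
    samples_t: list[Tree] = []
    samples_a: list[float] = []
    samples_l: list[float] = []

    for gen in range(1, config.generations + 1):
        move = moves[rng.choice(len(moves), p=weights)]
        proposed[move] += 1
        log_hastings = 0.0
        new_alpha = alpha
        backup = None
        dead_end = False
        dirty: Optional[set[int]] = set()

        if move == "nni":
            cands = ut.internal_edges()
            v = cands[rng.integers(len(cands))]
            which = int(rng.integers(2))
            backup = ("nni", v, which)
            ut.nni(v, which)
            dirty = ancestors(v)
        elif move == "spr":
            cands = [v for v in ut.edges() if ut.parent[v] != ut.root]
            v = cands[rng.integers(len(cands))]
            targets = ut.spr_targets(v)
            if not targets:
                dead_end = True   # no valid regraft edge: reject outright
            else:
                target = targets[rng.integers(len(targets))]
                p = ut.parent[v]
                (sib,) = [c for c in ut.children[p] if c != v]
                backup = ("full", ut.copy())
                merged, L = ut.spr(v, target, split_frac=rng.random())
                if merged > 0:
                    log_hastings = math.log(L) - math.log(merged)
                par_s = ut.parent[sib]
                dirty = ancestors(ut.parent[v])
                if par_s != ut.root:
                    dirty |= ancestors(par_s)
        elif move == "blen":
            edges = ut.edges()
            v = edges[rng.integers(len(edges))]
            m = math.exp(config.blen_multiplier_lambda * (rng.random() - 0.5))
            backup = ("blen", v, ut.blen[v])
            ut.blen[v] = ut.blen[v] * m
            log_hastings = math.log(m)
            if ut.parent[v] != ut.root:
                dirty = ancestors(ut.parent[v]) | {ut.parent[v]}
        else:  # alpha sliding window with reflection at zero
            da = config.alpha_window * (2.0 * rng.random() - 1.0)
            new_alpha = abs(alpha + da)
            if new_alpha == 0.0:
                new_alpha = 1e-12
            dirty = None

        if dead_end:
            if gen % config.sample_every == 0:
                samples_t.append(ut.to_tree(taxa))
                samples_a.append(alpha)
                samples_l.append(lnl)
            continue

        payload = None
        if use_lik:
            try:
                if dirty is None:
                    new_lnl, payload = cached.propose_alpha(
                        new_alpha if gamma_on else None)
                else:
                    new_lnl, payload = cached.propose(dirty)
            except ValueError:
                new_lnl = -np.inf
        else:
            new_lnl = 0.0
        new_lpr = log_prior(ut, new_alpha)
        log_r = (new_lnl + new_lpr) - (lnl + lpr) + log_hastings
        if math.log(rng.random()) < log_r:
            accepted[move] += 1
            lnl, lpr = new_lnl, new_lpr
            if use_lik:
                cached.accept(new_lnl, payload, full=dirty is None)
                if dirty is None:
                    cached.set_alpha(new_alpha if gamma_on else None)
            alpha = new_alpha
        else:
            if backup is not None:
                kind = backup[0]
                if kind == "nni":
                    ut.nni(backup[1], backup[2])
                elif kind == "blen":
                    ut.blen[backup[1]] = backup[2]
                else:
                    ut.assign(backup[1])

        if gen % config.sample_every == 0:
            samples_t.append(ut.to_tree(taxa))
            samples_a.append(alpha)
            samples_l.append(lnl)

    post_t = samples_t[total_samples - keep:]
    post_a = samples_a[total_samples - keep:]
    post_l = samples_l[total_samples - keep:]
    acc = {m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
           for m in moves}
    return ChainSample(post_t, post_a, post_l, acc, _split_frequencies(post_t))


def mcmc_run(matrix: CharacterMatrix, model: Optional[MkModel] = None,
             config: Optional[McmcConfig] = None,
             start_tree: Optional[Tree] = None) -> PosteriorSample:
    """Run ``config.n_chains`` independent MCMC chains and return the
    pooled posterior sample.  Chains are seeded deterministically from
    ``config.seed``; the whole run is reproducible."""
    model = model or MkModel(partition_mode="by_state_count")
    config = config or McmcConfig()
    config.validate()
    if matrix.n_taxa < 4:
        raise ValueError("MCMC requires at least 4 taxa")
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([0 if config.seed is None else config.seed, c])
        chains.append(_run_chain(matrix, model, config, rng, start_tree,
                                 chain_index=c))
    return PosteriorSample(chains, list(matrix.taxa))


def posterior_consensus(sample: PosteriorSample) -> Tree:
    """50% majority-rule consensus of the posterior topology sample; node
    supports are posterior probabilities (split frequencies)."""
    trees = sample.trees
    if not trees:
        raise ValueError("empty posterior sample")
    return majority_rule_consensus(trees, threshold=0.5)


@dataclass
class ConvergenceReport:
    asdsf: float
    flagged: bool
    n_splits: int
    threshold: float = 0.05


def convergence_diagnostics(sample: Union[PosteriorSample, Sequence[ChainSample]],
                            min_freq: float = 0.1,
                            threshold: float = 0.05) -> ConvergenceReport:
    """Average standard deviation of split frequencies (ASDSF) between
    independent chains; flagged (not failed) above the conventional 0.05."""
    chains = sample.chains if isinstance(sample, PosteriorSample) else list(sample)
    if len(chains) < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    freqs = [c.split_freqs for c in chains]
    splits = {b for f in freqs for b, v in f.items() if v >= min_freq}
    if not splits:
        return ConvergenceReport(0.0, False, 0, threshold)
    sds = []
    for b in splits:
        vals = np.array([f.get(b, 0.0) for f in freqs])
        sds.append(vals.std(ddof=1))
    asdsf = float(np.mean(sds))
    return ConvergenceReport(asdsf, asdsf > threshold, len(splits), threshold)
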