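"""Experiment orchestration: simulate replicate matrices per condition
(tree shape x character count), run the three inference engines with
support assessment, collapse weakly supported nodes, score against the
generating tree, and emit summary tables.

Scale defaults are desk-sized (tens of replicates, dozens of bootstrap
replicates, short chains); the study-sized numbers (1000 replicates,
250 bootstrap replicates, long chains) are reachable purely through
configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .bayes import McmcConfig, mcmc_run, posterior_consensus
from .metrics import (ReplicateResult, nodes_to_frame, results_to_frame,
                      score_replicate, summarize_experiment)
from .mk import MkModel, MLSearchConfig, bootstrap_ml, ml_search
from .parsimony import SearchConfig, bootstrap_parsimony, mp_search
from .simulate import (GeneratingTreeSpec, SimulationConfig, assemble_matrix,
                       make_generating_tree)
from .tree import Tree, collapse_by_support

log = logging.getLogger("mkphylo.driver")

__all__ = ["StudyConfig", "run_replicate", "run_cell", "run_study"]


@dataclass
class StudyConfig:
    shapes: tuple[str, ...] = ("symmetric", "asymmetric")
    n_chars_set: tuple[int, ...] = (100, 350, 1000)
    n_taxa: int = 32
    depth: float = 1.0
    replicates: int = 20
    bootstrap_reps: int = 50
    parsimony_starts: int = 5
    mcmc_generations: int = 6000
    mcmc_sample_every: int = 10
    mcmc_chains: int = 2
    mcmc_burnin: float = 0.25
    seed: int = 0
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shapes", "n_chars_set"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _replicate_seeds(config: StudyConfig, shape: str, n_chars: int,
                     replicate: int) -> tuple[np.random.Generator, list[int]]:
    """Deterministic per-replicate RNG stream, independent of execution
    order: keyed by (master seed, cell, replicate)."""
    cell = (config.shapes.index(shape), config.n_chars_set.index(n_chars)
            if n_chars in config.n_chars_set else n_chars)
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(cell[0], cell[1], replicate))
    ints = [int(x) for x in ss.generate_state(4, dtype=np.uint32) % (2 ** 31)]
    return np.random.default_rng(ss), ints


def run_replicate(config: StudyConfig, generating: Tree, shape: str,
                  n_chars: int, replicate: int) -> list[ReplicateResult]:
    """One replicate: simulate a matrix, infer with parsimony (+
    bootstrap), ML (+ bootstrap) and Bayesian MCMC (posterior
    probabilities), then score both the optimal and the <50%-support
    collapsed tree for each method: 6 result rows."""
    rng, ints = _replicate_seeds(config, shape, n_chars, replicate)
    sim = SimulationConfig(n_chars=n_chars)
    matrix = assemble_matrix(generating, sim, rng=rng)

    out: list[ReplicateResult] = []

    def score(tree: Tree, method: str, stage: str) -> None:
        out.append(score_replicate(tree, generating, stage, shape=shape,
                                   n_chars=n_chars, method=method,
                                   replicate=replicate))

    # parsimony
    p_cfg = SearchConfig(n_random_addition_starts=config.parsimony_starts,
                         seed=ints[0])
    p_res = mp_search(matrix, p_cfg)
    p_tree = bootstrap_parsimony(matrix, reps=config.bootstrap_reps,
                                 config=p_cfg, result=p_res)
    score(p_tree, "parsimony", "optimal")
    score(collapse_by_support(p_tree, 0.5), "parsimony", "collapsed_50")

    # maximum likelihood (single transition matrix, RAxML-style)
    ml_cfg = MLSearchConfig(seed=ints[1])
    ml_model = MkModel(partition_mode="single_matrix")
    ml_res = ml_search(matrix, ml_model, ml_cfg)
    ml_tree = bootstrap_ml(matrix, ml_model, reps=config.bootstrap_reps,
                           config=ml_cfg, result=ml_res)
    score(ml_tree, "ml", "optimal")
    score(collapse_by_support(ml_tree, 0.5), "ml", "collapsed_50")

    # Bayesian (characters partitioned by state count, MrBayes-style)
    b_cfg = McmcConfig(generations=config.mcmc_generations,
                       sample_every=config.mcmc_sample_every,
                       burnin_fraction=config.mcmc_burnin,
                       n_chains=config.mcmc_chains, seed=ints[2])
    sample = mcmc_run(matrix, MkModel(partition_mode="by_state_count"), b_cfg)
    cons = posterior_consensus(sample)
    score(cons, "bayesian", "optimal")
    score(collapse_by_support(cons, 0.5), "bayesian", "collapsed_50")
    return out


def run_cell(config: StudyConfig, shape: str, n_chars: int
             ) -> tuple[list[ReplicateResult], list[dict]]:
    """All replicates of one study cell; engine failures are logged and
    recorded, never silently dropped."""
    generating = make_generating_tree(
        GeneratingTreeSpec(shape=shape, n_taxa=config.n_taxa, depth=config.depth))
    results: list[ReplicateResult] = []
    failures: list[dict] = []
    for rep in range(config.replicates):
        t0 = time.perf_counter()
        try:
            results.extend(run_replicate(config, generating, shape, n_chars, rep))
        except Exception as exc:   # noqa: BLE001 - replicate-level fault barrier
            log.exception("replicate failed: %s %s rep %d", shape, n_chars, rep)
            failures.append({"shape": shape, "n_chars": n_chars,
                             "replicate": rep, "error": repr(exc)})
        log.info("cell %s/%d replicate %d done in %.1fs",
                 shape, n_chars, rep, time.perf_counter() - t0)
    return results, failures


def run_study(config: StudyConfig) -> dict:
    """Run every cell, write TSV summaries and a manifest; returns the
    summary tables.  Exit status handling for partial completion is the
    caller's job via the returned manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    all_results: list[ReplicateResult] = []
    all_failures: list[dict] = []
    for shape in config.shapes:
        for n_chars in config.n_chars_set:
            res, fail = run_cell(config, shape, n_chars)
            all_results.extend(res)
            all_failures.extend(fail)

    summaries = summarize_experiment(all_results)
    summaries["rf"].to_csv(out_dir / "table1_rf.tsv", sep="\t", index=False)
    summaries["resolution"].to_csv(out_dir / "table2_resolution.tsv",
                                   sep="\t", index=False)
    nodes_to_frame(all_results).to_csv(out_dir / "support_nodes.tsv",
                                       sep="\t", index=False)
    results_to_frame(all_results).to_csv(out_dir / "replicates.tsv",
                                         sep="\t", index=False)

    import mkphylo

    manifest = {
        "config": asdict(config),
        "version": getattr(mkphylo, "__version__", "unknown"),
        "n_results": len(all_results),
        "failures": all_failures,
        "runtime_seconds": round(time.time() - t_start, 2),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"summaries": summaries, "manifest": manifest,
            "results": all_results}
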