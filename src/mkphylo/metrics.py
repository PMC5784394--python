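"""Scoring estimated trees against the generating tree and summarising
simulation experiments: Robinson-Foulds accuracy, resolution, per-node
accuracy of supported clades, and median / 95%-interval tables.

Quantiles use linear interpolation between order statistics (numpy's
default), which is how fractional interval endpoints arise from
integer-valued RF distances over many replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree import Bipartition, Tree, bipartitions, resolution, rf_distance
from .tree import _leafsets

__all__ = [
    "NodeRecord",
    "ReplicateResult",
    "score_replicate",
    "support_accuracy_summary",
    "summarize_experiment",
    "results_to_frame",
    "nodes_to_frame",
]


@dataclass
class NodeRecord:
    bipartition: Bipartition
    support: Optional[float]
    accurate: bool


@dataclass
class ReplicateResult:
    shape: str              # generating tree shape
    n_chars: int
    method: str             # "parsimony" | "ml" | "bayesian"
    stage: str              # "optimal" | "collapsed_50"
    rf: int
    resolution: int
    nodes: list[NodeRecord]
    replicate: int = 0

    @property
    def condition(self) -> tuple:
        return (self.shape, self.n_chars, self.method, self.stage)


def score_replicate(estimated: Tree, generating: Tree, stage: str,
                    shape: str = "", n_chars: int = 0, method: str = "",
                    replicate: int = 0) -> ReplicateResult:
    """Score one estimated tree against its generating tree.

    rf is the Robinson-Foulds distance, resolution the internal-vertex
    count, and each non-trivial node of the estimate is recorded with
    its support and whether its bipartition occurs in the generating
    tree."""
    truth = bipartitions(generating)
    est = bipartitions(estimated)
    universe = estimated.taxa
    sets = _leafsets(estimated)
    nodes = []
    seen: set[Bipartition] = set()
    for node in estimated.preorder():
        if node.is_leaf or node is estimated.root:
            continue
        if not 2 <= len(sets[node]) <= len(universe) - 2:
            continue
        bip = Bipartition.from_leafset(sets[node], universe)
        if bip in seen:     # degree-2 root: both child edges carry one split
            continue
        seen.add(bip)
        nodes.append(NodeRecord(bip, node.support, bip in truth))
    return ReplicateResult(shape, n_chars, method, stage,
                           rf_distance(estimated, generating),
                           resolution(estimated), nodes, replicate)


def results_to_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"shape": r.shape, "n_chars": r.n_chars, "method": r.method,
         "stage": r.stage, "replicate": r.replicate, "rf": r.rf,
         "resolution": r.resolution}
        for r in results
    ])


def nodes_to_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for node in r.nodes:
            rows.append({"shape": r.shape, "n_chars": r.n_chars,
                         "method": r.method, "stage": r.stage,
                         "replicate": r.replicate,
                         "support": node.support,
                         "accurate": node.accurate})
    return pd.DataFrame(rows)


def support_accuracy_summary(results: Sequence[ReplicateResult],
                             thresholds: Sequence[float] = (0.5, 0.8)) -> pd.DataFrame:
    """Support-vs-accuracy section: per condition and threshold, counts
    of accurate/inaccurate nodes at or above the threshold, the
    proportion accurate among them, median supports by accuracy class,
    and the mean resolution of the condition's trees."""
    if not results:
        raise ValueError("no results to summarise")
    nodes = nodes_to_frame(results)
    res = results_to_frame(results)
    rows = []
    for cond, grp in nodes.groupby(["shape", "n_chars", "method", "stage"]):
        cond_res = res[(res[["shape", "n_chars", "method", "stage"]] ==
                        pd.Series(cond, index=["shape", "n_chars", "method", "stage"])).all(axis=1)]
        acc = grp[grp.accurate]
        inacc = grp[~grp.accurate]
        for thr in thresholds:
            with_support = grp.dropna(subset=["support"])
            high = with_support[with_support.support >= thr]
            n_high_acc = int(high.accurate.sum())
            n_high_inacc = int((~high.accurate).sum())
            rows.append({
                "shape": cond[0], "n_chars": cond[1], "method": cond[2],
                "stage": cond[3], "threshold": thr,
                "n_accurate_at_threshold": n_high_acc,
                "n_inaccurate_at_threshold": n_high_inacc,
                "prop_accurate_at_threshold": (
                    n_high_acc / (n_high_acc + n_high_inacc)
                    if (n_high_acc + n_high_inacc) else np.nan),
                "median_support_accurate": acc.support.median(),
                "median_support_inaccurate": inacc.support.median(),
                "mean_resolution": cond_res.resolution.mean(),
            })
    return pd.DataFrame(rows)


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (float(np.median(values)),
            float(np.quantile(values, 0.025)),
            float(np.quantile(values, 0.975)))


def summarize_experiment(results: Sequence[ReplicateResult]) -> dict[str, pd.DataFrame]:
    """Median and [2.5%, 97.5%] interval of RF and resolution per
    condition, keyed like the emitted accuracy and resolution tables."""
    frame = results_to_frame(results)
    if frame.empty:
        raise ValueError("no results to summarise")
    out = {}
    for metric in ("rf", "resolution"):
        rows = []
        for cond, grp in frame.groupby(["shape", "n_chars", "method", "stage"]):
            med, lo, hi = _median_iqr(grp[metric].to_numpy())
            rows.append({"shape": cond[0], "n_chars": cond[1],
                         "method": cond[2], "stage": cond[3],
                         "n": len(grp), "median": med,
                         "q2.5": lo, "q97.5": hi})
        out[metric] = pd.DataFrame(rows)
    return out
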