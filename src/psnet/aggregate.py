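"""Integrated patient similarity network: aggregation, pruning, separation.

After feature selection, the surviving feature networks are merged into a
single patient similarity network by taking the mean (or maximum) of each
patient pair's edge weights.  For the MEAN rule a pair absent from a network
contributes 0 with that network still counted in the denominator, so pairs
supported by many features dominate.  The merged network can be pruned to
its strongest edges (``top_x`` fraction retained) for visualisation and
topology statistics.

Class separation is quantified on the integrated network by converting
similarities to path lengths (length = 1/weight), computing all-pairs
shortest paths, and comparing within-class against between-class distances
with a one-sided Wilcoxon–Mann–Whitney test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.stats import mannwhitneyu

from .dataset import ValidationError
from .similarity import SimilarityNetwork

__all__ = ["AggregationParams", "SeparationStats", "aggregate_and_prune",
           "class_separation_stats"]


@dataclass
class AggregationParams:
    agg_fun: str = "MEAN"  # or "MAX"
    top_x: float = 1.0

    def __post_init__(self) -> None:
        if self.agg_fun not in ("MEAN", "MAX"):
            raise ValidationError(f"unknown agg_fun {self.agg_fun!r}", field="agg_fun")
        if not (0.0 < self.top_x <= 1.0):
            raise ValidationError("top_x must be in (0, 1]", field="top_x")


@dataclass
class SeparationStats:
    within: np.ndarray
    between: np.ndarray
    p_value: float | None
    unreachable_within: int
    unreachable_between: int
    tested: bool = True
    skip_reason: str = ""


def aggregate_and_prune(
    networks: Sequence[SimilarityNetwork] | Mapping[str, SimilarityNetwork],
    p: AggregationParams | None = None,
    name: str = "integrated",
) -> SimilarityNetwork:
    """MEAN/MAX aggregation of selected feature networks plus edge pruning.

    Keeps the top ``ceil(top_x * n_edges)`` edges by aggregated weight (ties
    broken by edge name for determinism).
    """
    p = p or AggregationParams()
    nets = list(networks.values()) if isinstance(networks, Mapping) else list(networks)
    if not nets:
        raise ValidationError("need at least one network", field="networks")
    agg: dict = {}
    nodes: set[str] = set()
    for net in nets:
        nodes |= net.nodes
        for e, w in net.edges.items():
            if p.agg_fun == "MEAN":
                agg[e] = agg.get(e, 0.0) + w / len(nets)
            else:
                agg[e] = max(agg.get(e, 0.0), w)
    out = SimilarityNetwork(name, nodes=nodes)
    if not agg:
        return out
    keep = math.ceil(p.top_x * len(agg))
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    out.edges = dict(ranked[:keep])
    return out


def class_separation_stats(
    net: SimilarityNetwork,
    labels: Mapping[str, str],
) -> SeparationStats:
    """Within- versus between-class shortest-path distances.

    Edge length is the reciprocal similarity (stronger similarity, shorter
    path).  Unreachable pairs are excluded from the test and counted.  The
    p-value is a one-sided Wilcoxon–Mann–Whitney test that within-class
    distances are stochastically smaller than between-class distances.
    """
    nodes = sorted(n for n in net.nodes if n in labels)
    if len(set(labels[n] for n in nodes)) < 2:
        raise ValidationError("need at least 2 classes among network nodes",
                              field="labels")
    index = {n: k for k, n in enumerate(nodes)}
    lengths = net.to_sparse(index).copy()
    lengths.data = 1.0 / lengths.data
    dist = dijkstra(lengths, directed=False)
    lab = np.array([labels[n] for n in nodes])
    iu, ju = np.triu_indices(len(nodes), k=1)
    same = lab[iu] == lab[ju]
    d = dist[iu, ju]
    fin = np.isfinite(d)
    within = d[same & fin]
    between = d[~same & fin]
    unreach_w = int((same & ~fin).sum())
    unreach_b = int((~same & ~fin).sum())
    if len(within) < 2 or len(between) < 2:
        return SeparationStats(within, between, None, unreach_w, unreach_b,
                               tested=False,
                               skip_reason="fewer than 2 finite distances in a group")
    stat = mannwhitneyu(within, between, alternative="less")
    return SeparationStats(within, between, float(stat.pvalue),
                           unreach_w, unreach_b)
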