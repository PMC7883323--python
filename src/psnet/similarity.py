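"""Patient similarity networks (PSNs): one weighted graph per feature.

Each feature — a pathway's worth of expression measures, a single clinical
variable, or a pathway-level set of mutated genes — is converted into an
undirected weighted graph whose nodes are patients and whose edge weights
quantify pairwise similarity under that feature's data.  Built-in metrics:

* ``pearson`` — pairwise Pearson correlation of the group's measure profiles,
  computed over pairwise-complete observations; negative correlations are
  clipped to zero (non-negative affinities are assumed downstream).
* ``normdiff`` — 1 - |x_a - x_b| / (observed range), for one continuous
  variable.
* ``scaled_euclidean`` — 1 - d(a,b) / max pairwise distance.
* ``binary`` — pathway co-mutation: all carriers of an event in the gene set
  form a clique with unit weights, provided there are at least
  ``min_carriers`` carriers (default 6); otherwise the feature is not created.

Custom metrics may be registered as callables with the same return contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import PatientDataset, GroupingRules, ValidationError

__all__ = [
    "SimilarityNetwork",
    "SparsifyParams",
    "pearson_profile_network",
    "continuous_variable_network",
    "binary_pathway_network",
    "sparsify_network",
    "build_feature_networks",
    "write_edge_list",
    "read_edge_list",
]

DEFAULT_MIN_CARRIERS = 6

Edge = tuple[str, str]


def _key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class SimilarityNetwork:
    """A named, weighted, undirected graph over patient identifiers.

    Edges are stored as a mapping from the sorted id pair to a finite,
    non-negative weight; self-edges are rejected.
    """

    name: str
    edges: dict[Edge, float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValidationError(f"{self.name}: self-edge on {a!r}", field="edges")
        if not math.isfinite(w) or w < 0:
            raise ValidationError(
                f"{self.name}: weight {w!r} for ({a},{b}) must be finite and >= 0",
                field="edges",
            )
        self.edges[_key(a, b)] = float(w)
        self.nodes.add(a)
        self.nodes.add(b)

    def weight(self, a: str, b: str) -> float:
        return self.edges.get(_key(a, b), 0.0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for (a, b) in self.edges if node in (a, b))

    def to_sparse(self, index: Mapping[str, int], n: int | None = None) -> sp.csr_matrix:
        """Symmetric CSR adjacency under a patient -> row index mapping.

        Nodes absent from ``index`` are dropped (used to restrict a network
        to the training cohort).
        """
        n = n if n is not None else len(index)
        rows, cols, vals = [], [], []
        for (a, b), w in self.edges.items():
            ia, ib = index.get(a), index.get(b)
            if ia is None or ib is None:
                continue
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g

    def restricted(self, keep: Iterable[str]) -> "SimilarityNetwork":
        keep = set(keep)
        net = SimilarityNetwork(self.name, nodes=self.nodes & keep)
        for (a, b), w in self.edges.items():
            if a in keep and b in keep:
                net.edges[(a, b)] = w
        return net


@dataclass
class SparsifyParams:
    """Edge filtering: drop weights below ``min_weight``, then per node keep
    only the ``max_degree`` strongest incident edges (an edge survives if
    either endpoint retains it)."""

    min_weight: float = 0.3
    max_degree: int = 50

    def __post_init__(self) -> None:
        if self.min_weight < 0:
            raise ValidationError("min_weight must be >= 0", field="min_weight")
        if self.max_degree < 1:
            raise ValidationError("max_degree must be positive", field="max_degree")


def pearson_profile_network(
    layer_matrix: pd.DataFrame,
    group: Sequence[str],
    name: str,
    *,
    clip_negative: bool = True,
) -> SimilarityNetwork:
    """PSN from Pearson correlation of grouped measure profiles.

    Correlations use pairwise-complete observations; a patient pair receives
    an edge only when it shares >= 2 observed measures, the correlation is
    defined (non-zero variance) and the clipped weight is positive.
    """
    present = [m for m in group if m in layer_matrix.index]
    if len(present) < 2:
        raise ValidationError(
            f"feature {name!r}: group resolves to {len(present)} measure(s); "
            "need at least 2",
            field=name,
        )
    sub = layer_matrix.loc[present].astype(float)
    # drop patients with no observations at all in this group
    sub = sub.loc[:, sub.notna().any(axis=0)]
    corr = sub.corr(method="pearson", min_periods=2)
    net = SimilarityNetwork(name, nodes=set(map(str, sub.columns)))
    cols = list(corr.columns)
    vals = corr.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = vals[i, j]
            if not np.isfinite(r):
                continue
            w = max(r, 0.0) if clip_negative else (r + 1.0) / 2.0
            if w > 0:
                net.add_edge(str(cols[i]), str(cols[j]), min(w, 1.0))
    return net


def continuous_variable_network(
    values: Mapping[str, float],
    metric: str,
    name: str,
) -> SimilarityNetwork:
    """PSN from one continuous variable.

    ``normdiff``: w(a,b) = 1 - |x_a - x_b| / (max - min) over the observed
    cohort.  ``scaled_euclidean``: w(a,b) = 1 - |x_a - x_b| / max pairwise
    distance (identical for a scalar variable up to the normalising constant).
    Patients with missing values are omitted, not imputed.
    """
    obs = {str(k): float(v) for k, v in values.items() if v is not None and np.isfinite(v)}
    if len(obs) < 2:
        raise ValidationError(
            f"feature {name!r}: fewer than 2 observed values", field=name
        )
    xs = np.array(list(obs.values()))
    span = xs.max() - xs.min()
    if metric == "normdiff":
        if span == 0:
            raise ValidationError(
                f"feature {name!r}: degenerate range (all values identical)",
                field=name,
            )
        denom = span
    elif metric == "scaled_euclidean":
        # max pairwise Euclidean distance of a scalar == range
        if span == 0:
            raise ValidationError(
                f"feature {name!r}: all values identical; distances undefined",
                field=name,
            )
        denom = span
    else:
        raise ValidationError(f"unknown continuous metric {metric!r}", field=name)
    ids = list(obs)
    net = SimilarityNetwork(name, nodes=set(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = 1.0 - abs(obs[ids[i]] - obs[ids[j]]) / denom
            if w > 0:
                net.add_edge(ids[i], ids[j], w)
    return net


def binary_pathway_network(
    events: Mapping[str, set[str] | Sequence[str]],
    gene_set: Iterable[str],
    name: str,
    min_carriers: int = DEFAULT_MIN_CARRIERS,
) -> SimilarityNetwork | None:
    """Pathway co-mutation clique: similarity 1 between any two carriers.

    Returns None when fewer than ``min_carriers`` patients carry an event in
    the gene set — the feature is simply not created, mirroring the carrier
    floor used for rare-variant features.
    """
    genes = set(gene_set)
    carriers = sorted(str(p) for p, gs in events.items() if genes & set(gs))
    if len(carriers) < min_carriers:
        return None
    net = SimilarityNetwork(name, nodes=set(carriers))
    for i in range(len(carriers)):
        for j in range(i + 1, len(carriers)):
            net.edges[_key(carriers[i], carriers[j])] = 1.0
    return net


def sparsify_network(net: SimilarityNetwork, p: SparsifyParams) -> SimilarityNetwork:
    """Threshold-and-cap edge filter; idempotent."""
    strong = {e: w for e, w in net.edges.items() if w >= p.min_weight}
    incident: dict[str, list[tuple[float, Edge]]] = {}
    for e, w in strong.items():
        for node in e:
            incident.setdefault(node, []).append((w, e))
    keep: set[Edge] = set()
    for node, lst in incident.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        keep.update(e for _, e in lst[: p.max_degree])
    out = SimilarityNetwork(net.name, nodes=set(net.nodes))
    out.edges = {e: strong[e] for e in keep}
    return out


MetricFn = Callable[..., SimilarityNetwork | None]


def build_feature_networks(
    ds: PatientDataset,
    rules: GroupingRules,
    metric_assignment: Mapping[str, str | MetricFn],
    restrict_to: Iterable[str] | None = None,
    *,
    sparsify: SparsifyParams | None = None,
    min_carriers: int = DEFAULT_MIN_CARRIERS,
) -> dict[str, SimilarityNetwork]:
    """Build one PSN per rule group across all layers.

    ``restrict_to`` limits the patients considered (train-only networks
    during feature selection).  Binary features below the carrier floor are
    absent from the result.  Per-feature errors are re-raised with the
    feature name attached.
    """
    keep = set(map(str, restrict_to)) if restrict_to is not None else None
    nets: dict[str, SimilarityNetwork] = {}
    for layer, groups in rules.items():
        if layer not in metric_assignment:
            raise ValidationError(f"no metric assigned to layer {layer!r}", field=layer)
        metric = metric_assignment[layer]
        if layer not in ds.assays:
            raise ValidationError(f"layer {layer!r} missing from dataset", field=layer)
        mat = ds.assays[layer]
        if keep is not None:
            mat = mat.loc[:, [c for c in mat.columns if str(c) in keep]]
        for feat, members in groups.items():
            if feat in nets:
                raise ValidationError(
                    f"duplicate feature name {feat!r} across layers", field=feat
                )
            try:
                net = _build_one(mat, metric, feat, members, min_carriers)
            except ValidationError:
                raise
            except Exception as exc:  # attach feature name to foreign errors
                raise ValidationError(f"feature {feat!r}: {exc}", field=feat) from exc
            if net is None:
                continue
            if sparsify is not None:
                net = sparsify_network(net, sparsify)
            nets[feat] = net
    return nets


def _build_one(
    mat: pd.DataFrame,
    metric: str | MetricFn,
    feat: str,
    members: Sequence[str],
    min_carriers: int,
) -> SimilarityNetwork | None:
    if callable(metric):
        return metric(mat, members, feat)
    if metric == "pearson":
        return pearson_profile_network(mat, members, feat)
    if metric in ("normdiff", "scaled_euclidean"):
        present = [m for m in members if m in mat.index]
        if len(present) != 1:
            raise ValidationError(
                f"feature {feat!r}: {metric} expects exactly one measure per "
                f"group, got {len(present)}",
                field=feat,
            )
        row = mat.loc[present[0]]
        values = {str(c): row[c] for c in mat.columns if pd.notna(row[c])}
        return continuous_variable_network(values, metric, feat)
    if metric == "binary":
        events = {
            str(c): set(mat.index[mat[c].fillna(0).to_numpy() > 0]) for c in mat.columns
        }
        return binary_pathway_network(events, members, feat, min_carriers)
    raise ValidationError(f"unknown metric {metric!r}", field=feat)


def write_edge_list(net: SimilarityNetwork, path) -> None:
    """Serialize as ``id_a <TAB> id_b <TAB> weight`` (6 significant digits)."""
    with open(path, "w") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def read_edge_list(path, name: str | None = None) -> SimilarityNetwork:
    import os

    name = name or os.path.splitext(os.path.basename(str(path)))[0]
    net = SimilarityNetwork(name)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{ln}: expected 3 tab-separated fields", field="edges"
                )
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{ln}: bad weight {parts[2]!r}", field="edges"
                ) from exc
            net.add_edge(parts[0], parts[1], w)
    return net
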