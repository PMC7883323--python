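"""Synthetic cohorts with planted class structure.

These generators produce every input the pipelines consume — labelled
multi-assay datasets with grouped measures, sparse genetic event tables with
case-enriched pathways, and gene–gene interaction networks with binary
mutation profiles — together with a *truth record* naming the planted
discriminative features, so recovery can be checked end to end.

Continuous layers follow a location-shift model: every group of measures
shares a latent per-measure pattern (so patients correlate positively within
any group, as co-regulated genes do), and discriminative groups additionally
carry a class-specific offset pattern whose magnitude is ``effect_size``
standard deviations, splitting within-class from between-class profile
correlation.  Residual noise has unit variance.  Real-data features this
model does not emulate: heavy-tailed expression, batch effects, correlated
noise across groups, and label noise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PatientDataset
from .io import GeneSetCollection

__all__ = [
    "generate_synthetic_dataset",
    "generate_synthetic_events",
    "generate_gene_interaction_network",
    "generate_mutation_matrix",
]


def generate_synthetic_dataset(
    n_patients: int = 200,
    classes: Sequence[str] = ("case", "control"),
    layers: Mapping[str, dict] | None = None,
    n_discriminative: int = 1,
    effect_size: float = 2.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[PatientDataset, dict, dict]:
    """Labelled multi-assay dataset with planted discriminative groups.

    ``layers`` maps layer name to ``{"n_features": int, "group_size": int,
    "metric": str}``; the default is a single expression-like layer with 20
    groups of 10 measures scored by profile correlation.  The first
    ``n_discriminative`` groups of each layer carry the class effect.

    Returns ``(dataset, rules, truth)`` where ``truth["discriminative"]``
    lists the planted feature names and ``truth["metrics"]`` is the layer ->
    metric assignment for the pipelines.
    """
    if n_patients < 2 * len(classes):
        raise ValueError("need at least 2 patients per class")
    layers = layers or {
        "expression": {"n_features": 20, "group_size": 10, "metric": "pearson"}
    }
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(1, n_patients + 1)]
    labels = {pid: classes[i % len(classes)] for i, pid in enumerate(ids)}
    class_idx = np.array([i % len(classes) for i in range(n_patients)])
    # centered class offsets, e.g. +1/2, -1/2 for two classes
    offsets = np.arange(len(classes), dtype=float)
    offsets -= offsets.mean()
    offsets /= max(np.abs(offsets).max(), 1.0)

    assays: dict[str, pd.DataFrame] = {}
    rules: dict[str, dict[str, list[str]]] = {}
    metrics: dict[str, str] = {}
    planted: list[str] = []
    for layer, spec in layers.items():
        n_feat = int(spec.get("n_features", 20))
        gsize = int(spec.get("group_size", 10))
        metrics[layer] = str(spec.get("metric", "pearson"))
        rows = []
        names = []
        groups: dict[str, list[str]] = {}
        for g in range(n_feat):
            feat = f"{layer}_grp{g:02d}"
            measures = [f"{layer}_g{g:02d}m{m:02d}" for m in range(gsize)]
            groups[feat] = measures
            shared = rng.normal(size=gsize)  # latent co-regulation pattern
            block = shared[:, None] + rng.normal(size=(gsize, n_patients))
            if g < n_discriminative:
                pattern = rng.choice([-1.0, 1.0], size=gsize)
                block += effect_size * pattern[:, None] * offsets[class_idx][None, :]
                planted.append(feat)
            rows.append(block)
            names.extend(measures)
        mat = pd.DataFrame(np.vstack(rows), index=names, columns=ids)
        if missing_rate > 0:
            mask = rng.random(mat.shape) < missing_rate
            mat = mat.mask(mask)
        assays[layer] = mat
        rules[layer] = groups
    ds = PatientDataset(ids=ids, labels=labels, assays=assays)
    truth = {"discriminative": planted, "metrics": metrics,
             "effect_size": effect_size, "seed": seed}
    return ds, rules, truth


def generate_synthetic_events(
    n_patients: int = 300,
    n_pathways: int = 30,
    genes_per_pathway: int = 20,
    n_enriched: int = 1,
    case_event_rate: float = 0.4,
    control_event_rate: float = 0.05,
    background_rate: float = 0.05,
    classes: Sequence[str] = ("case", "control"),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, set[str]], GeneSetCollection, dict]:
    """Sparse genetic events with case-enriched pathways.

    Every pathway has a background chance of an event in any patient; the
    first ``n_enriched`` pathways additionally hit cases at
    ``case_event_rate`` and controls at ``control_event_rate``.  Returns
    ``(labels, events, gene_sets, truth)`` where events maps patient ->
    mutated gene symbols.
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i:04d}" for i in range(1, n_patients + 1)]
    labels = {pid: classes[i % len(classes)] for i, pid in enumerate(ids)}
    coll = GeneSetCollection()
    pathways: dict[str, list[str]] = {}
    for p in range(n_pathways):
        nm = f"PATHWAY_{p:02d}"
        genes = [f"G{p:02d}_{k:02d}" for k in range(genes_per_pathway)]
        pathways[nm] = genes
        coll.sets[nm] = ("synthetic", genes)
    enriched = [f"PATHWAY_{p:02d}" for p in range(n_enriched)]
    events: dict[str, set[str]] = {pid: set() for pid in ids}
    for nm, genes in pathways.items():
        for pid in ids:
            rate = background_rate
            if nm in enriched:
                rate = (case_event_rate if labels[pid] == classes[0]
                        else control_event_rate)
            if rng.random() < rate:
                events[pid].add(genes[rng.integers(len(genes))])
    truth = {"enriched": enriched, "seed": seed}
    return labels, events, coll, truth


def generate_gene_interaction_network(
    n_genes: int = 50, edge_prob: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Symmetric binary gene-gene network (Erdos-Renyi), zero diagonal."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{k:03d}" for k in range(n_genes)]
    upper = rng.random((n_genes, n_genes)) < edge_prob
    A = np.triu(upper, k=1)
    A = (A | A.T).astype(int)
    return pd.DataFrame(A, index=genes, columns=genes)


def generate_mutation_matrix(
    genes: Sequence[str],
    n_patients: int = 20,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary gene x patient mutation matrix; every patient gets >= 1 hit."""
    rng = np.random.default_rng(seed)
    pats = [f"S{i:03d}" for i in range(1, n_patients + 1)]
    M = (rng.random((len(genes), n_patients)) < mutation_rate).astype(int)
    for j in range(n_patients):
        if M[:, j].sum() == 0:
            M[rng.integers(len(genes)), j] = 1
    return pd.DataFrame(M, index=list(genes), columns=pats)
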