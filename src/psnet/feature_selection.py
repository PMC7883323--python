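"""Feature scoring, consensus calling and label enrichment.

A feature's score in one train/test split is the number of integration
queries (out of ``feat_score_max``) in which its network received a positive
regression weight.  Features are then accepted by consensus across splits
(score >= ``fs_cutoff`` in at least ``fs_pct_pass`` of the splits), or, in
the sparse genetic workflow, summed across splits into a cumulative score
with maximum ``num_splits * feat_score_max``.

Label enrichment is the permutation filter used for rare-variant features:
a network's *bias* is ``(n_case - n_control) / (n_case + n_control)`` over
its member patients (+1 if all members are cases, -1 if all controls, 0 if
balanced), and its empirical p-value is the proportion of label permutations
whose bias is at least as large as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataset import (
    PatientDataset,
    GroupingRules,
    PredictorConfig,
    ValidationError,
    resample_training,
)
from .integration import QueryContext, solve_network_weights
from .similarity import SimilarityNetwork, build_feature_networks

__all__ = [
    "EnrichmentResult",
    "score_features_one_split",
    "call_feature_selection",
    "label_enrichment",
    "label_bias",
    "cumulative_scores",
    "write_score_table",
]

DEFAULT_ENRICHMENT_THRESHOLD = 0.07


@dataclass
class EnrichmentResult:
    network: str
    bias: float
    p_value: float
    passed: bool


def score_features_one_split(
    train_ds: PatientDataset,
    rules: GroupingRules,
    metric_assignment: Mapping[str, object],
    class_label: str,
    cfg: PredictorConfig,
    seed: int,
    networks: Mapping[str, SimilarityNetwork] | None = None,
    ridge: float = 1.0,
) -> dict[str, int]:
    """Score every feature for one class within one train/test split.

    Builds train-only networks (unless pre-built ones are passed), then runs
    ``feat_score_max`` integration queries on resampled subsets of the
    class's training patients against the other classes' training patients.
    A feature's score is the number of queries in which it earned a positive
    weight.
    """
    class_ids = train_ds.ids_of_class(class_label)
    if not class_ids:
        raise ValidationError(f"no training patients in class {class_label!r}",
                              field="class_label")
    if cfg.resampling_scheme == "holdout" and len(class_ids) < cfg.feat_score_max:
        raise ValidationError(
            f"class {class_label!r} has {len(class_ids)} training members; "
            f"holdout resampling needs at least feat_score_max={cfg.feat_score_max}",
            field="class_label",
        )
    background = [i for i in train_ds.labelled_ids()
                  if train_ds.labels[i] != class_label]
    if not background:
        raise ValidationError("no background patients (single-class training set)",
                              field="class_label")
    if networks is None:
        networks = build_feature_networks(
            train_ds, rules, metric_assignment, restrict_to=train_ds.ids
        )
    scores = {nm: 0 for nm in networks}
    for it in range(1, cfg.feat_score_max + 1):
        query = resample_training(
            class_ids, cfg.resampling_scheme, cfg.feat_score_max, it, seed,
            cfg.montecarlo_fraction,
        )
        ctx = QueryContext(
            query_ids=list(query),
            background_ids=list(background),
            candidate_networks=dict(networks),
        )
        try:
            fit = solve_network_weights(ctx, ridge=ridge)
        except ValidationError as exc:
            raise ValidationError(
                f"query {it} for class {class_label!r}: {exc}", field=exc.field
            ) from exc
        for nm in fit.positive():
            scores[nm] += 1
    return scores


def call_feature_selection(
    tbl: pd.DataFrame,
    fs_cutoff: int,
    fs_pct_pass: float,
) -> list[str]:
    """Consensus feature calling across train/test splits.

    ``tbl`` is a feature x split table of integer scores (NaN = feature never
    weighted in that split, counted as below cutoff).  A feature is selected
    when the fraction of splits with score >= ``fs_cutoff`` is at least
    ``fs_pct_pass``; ``fs_pct_pass = 0`` means "at least one split".
    """
    if fs_cutoff < 1:
        raise ValueError("fs_cutoff must be >= 1")
    if tbl.shape[1] < 1:
        raise ValueError("need at least one split column")
    if tbl.empty:
        return []
    hits = (tbl.fillna(-1) >= fs_cutoff).sum(axis=1)
    n_splits = tbl.shape[1]
    if fs_pct_pass <= 0:
        mask = hits >= 1
    else:
        mask = hits / n_splits >= fs_pct_pass
    return [str(f) for f in tbl.index[mask]]


def label_bias(
    members: Sequence[str], labels: Mapping[str, str], positive_label: str
) -> float:
    """(n+ - n-)/(n+ + n-) over a network's member patients."""
    n_pos = sum(1 for m in members if labels[m] == positive_label)
    n_neg = len(members) - n_pos
    if n_pos + n_neg == 0:
        raise ValidationError("bias undefined for an empty member set", field="members")
    return (n_pos - n_neg) / (n_pos + n_neg)


def label_enrichment(
    networks: Mapping[str, SimilarityNetwork],
    labels: Mapping[str, str],
    positive_label: str,
    num_perms: int = 50,
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
    seed: int = 0,
    exact: bool = False,
) -> dict[str, EnrichmentResult]:
    """Permutation filter on member-label bias.

    Labels are shuffled over the full cohort while each network's membership
    stays fixed; the empirical p-value is
    ``(1 + #{permutations with bias >= observed}) / (num_perms + 1)`` (the +1
    correction keeps p strictly positive so small permutation counts remain
    usable against the default 0.07 threshold).  With ``exact=True`` the
    permutation distribution is enumerated exhaustively instead: the member
    positive count under shuffling is hypergeometric, so the exact p is its
    upper tail, without the +1 correction.  Networks with no member patients
    are excluded with a warning.
    """
    if num_perms < 1:
        raise ValueError("num_perms must be >= 1")
    cohort = sorted(labels)
    lab_arr = np.array([labels[c] for c in cohort])
    if positive_label not in lab_arr:
        raise ValidationError(f"label {positive_label!r} absent from cohort",
                              field="positive_label")
    if len(set(lab_arr)) < 2:
        raise ValidationError("cohort must contain both labels", field="labels")
    pos_index = {c for c, l in zip(cohort, lab_arr) if l == positive_label}
    K = len(pos_index)
    N = len(cohort)

    members_of: dict[str, list[str]] = {}
    for nm, net in networks.items():
        mem = [n for n in sorted(net.nodes) if n in labels]
        if not mem:
            warnings.warn(f"network {nm!r} has no labelled members; excluded "
                          "from enrichment")
            continue
        members_of[nm] = mem

    results: dict[str, EnrichmentResult] = {}
    if exact:
        for nm, mem in members_of.items():
            m = len(mem)
            x_obs = sum(1 for p in mem if p in pos_index)
            # bias is monotone in the member positive count, so the tail of
            # the hypergeometric count distribution is the exact p-value
            p = float(hypergeom.sf(x_obs - 1, N, K, m))
            bias = (2 * x_obs - m) / m
            results[nm] = EnrichmentResult(nm, bias, p, p < threshold)
        return results

    rng = np.random.default_rng(seed)
    pos_of = {c: i for i, c in enumerate(cohort)}
    member_idx = {
        nm: np.array([pos_of[p] for p in mem]) for nm, mem in members_of.items()
    }
    obs_bias = {nm: label_bias(mem, labels, positive_label)
                for nm, mem in members_of.items()}
    exceed = {nm: 0 for nm in members_of}
    is_pos = np.array([c in pos_index for c in cohort])
    for _ in range(num_perms):
        perm = rng.permutation(N)
        pos_perm = is_pos[perm]
        for nm, idx in member_idx.items():
            m = len(idx)
            x = int(pos_perm[idx].sum())
            if (2 * x - m) / m >= obs_bias[nm] - 1e-12:
                exceed[nm] += 1
    for nm in members_of:
        p = (1 + exceed[nm]) / (num_perms + 1)
        results[nm] = EnrichmentResult(nm, obs_bias[nm], p, p < threshold)
    return results


def cumulative_scores(
    per_split_scores: Sequence[Mapping[str, int]],
) -> dict[str, int]:
    """Sum feature scores across splits (missing = 0).

    With ``num_splits`` splits and per-split maximum ``feat_score_max``, a
    feature can score as high as ``num_splits * feat_score_max``.
    """
    if not per_split_scores:
        raise ValueError("need at least one split")
    total: dict[str, int] = {}
    for col in per_split_scores:
        for nm, s in col.items():
            total[nm] = total.get(nm, 0) + int(s)
    return total


def write_score_table(scores: Mapping[str, int], path) -> None:
    """Tab-delimited ``PATHWAY_NAME <TAB> SCORE`` per split."""
    with open(path, "w") as fh:
        fh.write("PATHWAY_NAME\tSCORE\n")
        for nm in sorted(scores):
            fh.write(f"{nm}\t{scores[nm]}\n")
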