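"""Classification of held-out patients.

Dense workflow: for each class, the feature networks that passed selection
are rebuilt over training *and* test patients, integrated with equal
weights (weights are not re-fitted on the joint cohort — that would leak
test labels), and training membership in the class is propagated over the
integrated network.  Each test patient's class score is the normalized rank
of their propagation score among test patients, and the predicted class is
the argmax (ties broken by lexicographic class order).

Sparse workflow: a patient is called a case at a given score cutoff when
they carry a genetic event in at least one pathway that passed feature
selection at that cutoff; sweeping the cutoff yields a performance table of
confusion counts.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import PatientDataset, GroupingRules, ValidationError
from .integration import combine_networks, propagate_labels
from .similarity import SimilarityNetwork, build_feature_networks

__all__ = ["classify_by_propagation", "sparse_pathway_classify"]

SCORE_SUFFIX = "_SCORE"


def classify_by_propagation(
    ds: PatientDataset,
    rules: GroupingRules,
    metric_assignment: Mapping[str, object],
    selected_features_per_class: Mapping[str, Sequence[str]],
    train_labels: Mapping[str, str],
    test_ids: Sequence[str],
    lam: float = 1.0,
    networks: Mapping[str, SimilarityNetwork] | None = None,
) -> pd.DataFrame:
    """Score and label test patients by per-class label propagation.

    Returns the prediction table with one row per test patient: ``ID``,
    ``STATUS`` (truth, if known), ``TT_STATUS``, one ``<class>_SCORE``
    column per class, and ``PRED_CLASS``.
    """
    classes = sorted(set(train_labels.values()))
    test_ids = [str(t) for t in test_ids]
    if not test_ids:
        raise ValidationError("no test patients", field="test_ids")
    for cls in classes:
        feats = selected_features_per_class.get(cls, [])
        if not feats:
            raise ValidationError(
                f"class {cls!r} has no selected features", field="selected_features"
            )
        if not any(l == cls for l in train_labels.values()):
            raise ValidationError(
                f"class {cls!r} has no training members", field="train_labels"
            )

    prior_ids = list(dict.fromkeys(list(train_labels) + test_ids))
    if networks is None:
        needed = sorted({f for fs in selected_features_per_class.values() for f in fs})
        all_rules = {
            layer: {f: g for f, g in groups.items() if f in needed}
            for layer, groups in rules.items()
        }
        all_rules = {l: g for l, g in all_rules.items() if g}
        networks = build_feature_networks(
            ds, all_rules, metric_assignment, restrict_to=prior_ids
        )
    else:
        networks = {nm: net.restricted(prior_ids) for nm, net in networks.items()}
    scores = pd.DataFrame(index=test_ids, columns=classes, dtype=float)
    for cls in classes:
        feats = [f for f in selected_features_per_class[cls] if f in networks]
        if not feats:
            warnings.warn(f"class {cls!r}: no selected network could be built; "
                          "all test scores set to 0")
            scores[cls] = 0.0
            continue
        nets = {f: networks[f] for f in feats}
        weights = {f: 1.0 / len(feats) for f in feats}
        integrated = combine_networks(weights, nets, name=f"integrated_{cls}")
        prior = {pid: 0.0 for pid in prior_ids}
        for pid, lab in train_labels.items():
            if lab == cls:
                prior[pid] = 1.0
        prop = propagate_labels(integrated, prior, lam=lam)
        raw = np.empty(len(test_ids))
        for k, t in enumerate(test_ids):
            if t not in integrated.nodes:
                warnings.warn(
                    f"test patient {t!r} absent from every selected network of "
                    f"class {cls!r}; scored 0"
                )
            raw[k] = prop.scores.get(t, 0.0)
        if len(test_ids) == 1:
            scores[cls] = 1.0
        else:
            ranks = rankdata(raw, method="average")
            scores[cls] = (ranks - 1.0) / (len(test_ids) - 1.0)

    pred = scores.idxmax(axis=1)  # idxmax takes the first (lexicographic) max
    rows = {
        "ID": test_ids,
        "STATUS": [ds.labels.get(t, "") for t in test_ids],
        "TT_STATUS": ["TEST"] * len(test_ids),
    }
    table = pd.DataFrame(rows)
    for cls in classes:
        table[cls + SCORE_SUFFIX] = scores[cls].to_numpy()
    table["PRED_CLASS"] = pred.to_numpy()
    return table


def sparse_pathway_classify(
    test_events: Mapping[str, Iterable[str]],
    selected_by_cutoff: Mapping[int, Iterable[str]],
    pathway_genes: Mapping[str, Iterable[str]],
    labels: Mapping[str, str],
    positive_label: str,
) -> pd.DataFrame:
    """Confusion counts at every feature-score cutoff (sparse workflow).

    At each cutoff, a patient is predicted ``case`` iff one of their event
    genes belongs to a pathway selected at that cutoff.  Cutoffs must form a
    descending-inclusion family: a higher cutoff selects a subset of the
    pathways of any lower one, which makes tp and fp non-increasing in the
    cutoff.
    """
    cutoffs = sorted(selected_by_cutoff)
    sel = {c: set(selected_by_cutoff[c]) for c in cutoffs}
    for lo, hi in zip(cutoffs, cutoffs[1:]):
        if not sel[hi] <= sel[lo]:
            raise ValidationError(
                f"selected pathways at cutoff {hi} are not a subset of those at "
                f"cutoff {lo}",
                field="selected_by_cutoff",
            )
    gene_sets = {p: set(g) for p, g in pathway_genes.items()}
    patients = sorted(labels)
    truth = {p: labels[p] == positive_label for p in patients}
    events = {p: set(test_events.get(p, ())) for p in patients}
    rows = []
    for c in cutoffs:
        selected_genes_by_path = [gene_sets.get(p, set()) for p in sel[c]]
        tp = fp = tn = fn = 0
        for p in patients:
            is_case = any(events[p] & gs for gs in selected_genes_by_path)
            if is_case and truth[p]:
                tp += 1
            elif is_case:
                fp += 1
            elif truth[p]:
                fn += 1
            else:
                tn += 1
        rows.append({"score": c, "tp": tp, "fp": fp, "tn": tn, "fn": fn})
    return pd.DataFrame(rows)
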