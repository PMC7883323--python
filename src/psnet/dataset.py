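"""Core containers for multi-modal patient data and predictor configuration.

A patient cohort is represented by a :class:`PatientDataset`: a list of patient
identifiers, a ``STATUS`` label per patient, and one numeric assay matrix per
data layer (rows are measures such as genes or clinical variables, columns are
patients).  Patients may be absent from individual layers — that is the
supported missing-data case; entries inside a layer may also be NaN.

Grouping rules describe how measures within each layer are grouped into
*features*: every group later becomes one patient similarity network (e.g. one
pathway's genes, or a single clinical variable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientDataset",
    "GroupingRules",
    "PredictorConfig",
    "ValidationError",
    "ValidationReport",
    "validate_dataset",
    "split_train_test",
    "resample_training",
    "dedupe_patients",
]

#: Reserved layer name for variables taken from the patient metadata table.
CLINICAL_LAYER = "clinical"

TRAIN = "TRAIN"
TEST = "TEST"


class ValidationError(ValueError):
    """A fatal problem with a dataset or its grouping rules.

    Attributes
    ----------
    field : str
        Name of the offending field (patient ID, layer, group ...).
    """

    def __init__(self, message: str, field: str = ""):
        super().__init__(message)
        self.field = field


@dataclass
class PatientDataset:
    """Labelled multi-modal patient data.

    Parameters
    ----------
    ids : sequence of str
        Unique patient identifiers.
    labels : mapping id -> str
        Class label (STATUS) per patient.  Every labelled patient must appear
        in ``ids``.
    assays : mapping layer name -> DataFrame
        One numeric matrix per layer, rows = measures, columns = patient ids.
        Columns must be a subset of ``ids``; NaN entries are allowed.
    """

    ids: list[str]
    labels: dict[str, str]
    assays: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def labelled_ids(self) -> list[str]:
        return [i for i in self.ids if i in self.labels]

    def ids_of_class(self, label: str) -> list[str]:
        return [i for i in self.ids if self.labels.get(i) == label]

    def subset(self, keep_ids: Sequence[str]) -> "PatientDataset":
        """Restrict the dataset to ``keep_ids`` (order preserved)."""
        keep = [i for i in self.ids if i in set(keep_ids)]
        assays = {
            name: mat.loc[:, [c for c in mat.columns if c in set(keep)]]
            for name, mat in self.assays.items()
        }
        labels = {i: self.labels[i] for i in keep if i in self.labels}
        return PatientDataset(ids=keep, labels=labels, assays=assays)

    @staticmethod
    def merge(a: "PatientDataset", b: "PatientDataset") -> "PatientDataset":
        """Concatenate two cohorts with disjoint patient ids."""
        overlap = set(a.ids) & set(b.ids)
        if overlap:
            raise ValidationError(
                f"cannot merge datasets sharing patient ids: {sorted(overlap)[:5]}",
                field="ids",
            )
        assays: dict[str, pd.DataFrame] = {}
        for name in {*a.assays, *b.assays}:
            parts = [d.assays[name] for d in (a, b) if name in d.assays]
            assays[name] = pd.concat(parts, axis=1) if len(parts) > 1 else parts[0]
        return PatientDataset(
            ids=list(a.ids) + list(b.ids),
            labels={**a.labels, **b.labels},
            assays=assays,
        )


#: layer name -> feature name -> list of measure identifiers
GroupingRules = Mapping[str, Mapping[str, Sequence[str]]]


@dataclass
class PredictorConfig:
    """Settings of the feature-scoring / classification loop.

    ``feat_score_max`` is the number of integration queries run per class in
    one train/test split, and hence the maximum score a feature can earn in
    that split.  ``feat_sel_cutoff`` is the minimum score a feature needs to
    be used for classifying that split's test patients.
    """

    num_splits: int = 10
    feat_score_max: int = 10
    feat_sel_cutoff: int = 9
    train_fraction: float = 0.8
    resampling_scheme: str = "holdout"  # or "montecarlo"
    montecarlo_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.num_splits < 1:
            raise ValidationError("num_splits must be positive", field="num_splits")
        if self.feat_score_max < 1:
            raise ValidationError("feat_score_max must be positive", field="feat_score_max")
        if not (1 <= self.feat_sel_cutoff <= self.feat_score_max):
            raise ValidationError(
                "feat_sel_cutoff must lie in [1, feat_score_max]",
                field="feat_sel_cutoff",
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)", field="train_fraction")
        if self.resampling_scheme not in ("holdout", "montecarlo"):
            raise ValidationError(
                f"unknown resampling scheme {self.resampling_scheme!r}",
                field="resampling_scheme",
            )


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_dataset(
    ds: PatientDataset,
    rules: GroupingRules | None = None,
    *,
    raise_on_error: bool = False,
) -> ValidationReport:
    """Check ID/STATUS conventions and rule/assay name agreement.

    Fatal problems (duplicate ids, empty labels, unknown layer names, empty
    groups) go into ``report.problems``; measures named in a rule but absent
    from the layer matrix are warnings only — the feature is later built from
    the present measures.
    """
    rep = ValidationReport()
    if not ds.ids:
        rep.problems.append("ids: dataset has no patients")
    seen: set[str] = set()
    for pid in ds.ids:
        if pid in seen:
            rep.problems.append(f"ids: duplicate patient ID {pid!r}")
        seen.add(pid)
    if not ds.labels:
        rep.problems.append("labels: no patient labels (STATUS) provided")
    for pid in ds.labels:
        if pid not in seen:
            rep.problems.append(f"labels: labelled patient {pid!r} not in ids")
    for layer, mat in ds.assays.items():
        unknown = [c for c in mat.columns if c not in seen]
        if unknown:
            rep.problems.append(
                f"assays[{layer}]: columns not in ids: {sorted(map(str, unknown))[:5]}"
            )
    if rules is not None:
        known_layers = set(ds.assays) | {CLINICAL_LAYER}
        for layer, groups in rules.items():
            if layer not in known_layers:
                rep.problems.append(f"rules: unknown layer {layer!r}")
                continue
            for feat, members in groups.items():
                if len(members) == 0:
                    rep.problems.append(f"rules[{layer}][{feat}]: empty group")
                elif layer in ds.assays:
                    present = set(ds.assays[layer].index)
                    missing = [m for m in members if m not in present]
                    if missing:
                        rep.warnings.append(
                            f"rules[{layer}][{feat}]: {len(missing)} measure(s) "
                            f"absent from layer (e.g. {missing[0]!r})"
                        )
    if raise_on_error and rep.problems:
        first = rep.problems[0]
        raise ValidationError("; ".join(rep.problems), field=first.split(":", 1)[0])
    return rep


def split_train_test(
    ds: PatientDataset,
    cfg: PredictorConfig,
    seed: int,
) -> dict[str, str]:
    """Stratified train/test split of the labelled patients.

    Per class, ``round(train_fraction * class size)`` patients (clamped so
    both sides are non-empty) go to TRAIN.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in ds.classes:
        members = ds.ids_of_class(label)
        if len(members) < 2:
            raise ValidationError(
                f"class {label!r} has fewer than 2 members", field="labels"
            )
        n_train = int(round(cfg.train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        order = rng.permutation(len(members))
        for k, idx in enumerate(order):
            assignment[members[idx]] = TRAIN if k < n_train else TEST
    return assignment


def resample_training(
    train_ids_of_class: Sequence[str],
    scheme: str,
    feat_score_max: int,
    iteration: int,
    seed: int,
    montecarlo_fraction: float = 0.8,
) -> list[str]:
    """Query subsample of one class's training patients for iteration ``i``.

    holdout
        Ids are shuffled once with ``seed`` and cut into ``feat_score_max``
        nearly-equal contiguous blocks; iteration ``i`` omits block ``i``, so
        each query uses roughly ``1 - 1/feat_score_max`` of the class.  With
        ``feat_score_max == 1`` no holdout is possible and the full class is
        returned.
    montecarlo
        Each iteration independently draws ``montecarlo_fraction`` of the
        class without replacement (seeded per iteration).
    """
    ids = list(train_ids_of_class)
    if not ids:
        raise ValidationError("cannot resample an empty class", field="train_ids")
    if not (1 <= iteration <= feat_score_max):
        raise ValueError(f"iteration must be in [1, {feat_score_max}]")
    if scheme == "holdout":
        if feat_score_max == 1:
            return ids
        rng = np.random.default_rng(seed)
        order = [ids[k] for k in rng.permutation(len(ids))]
        bounds = np.linspace(0, len(ids), feat_score_max + 1).round().astype(int)
        lo, hi = bounds[iteration - 1], bounds[iteration]
        return order[:lo] + order[hi:]
    if scheme == "montecarlo":
        rng = np.random.default_rng([seed, iteration])
        n = max(1, int(round(montecarlo_fraction * len(ids))))
        picked = rng.choice(len(ids), size=n, replace=False)
        return [ids[k] for k in sorted(picked)]
    raise ValidationError(f"unknown resampling scheme {scheme!r}", field="scheme")


def dedupe_patients(meta: pd.DataFrame, id_col: str = "ID") -> pd.DataFrame:
    """Keep the first metadata record per patient ID."""
    return meta.loc[~meta[id_col].duplicated()].copy()
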