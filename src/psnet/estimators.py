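"""Scikit-learn style estimators over the patient-similarity-network core.

:class:`PSNClassifier` runs the dense workflow: repeated stratified
train/test splits, per-class feature scoring by regularized network
integration on training subsamples, selection of high-scoring features, and
classification of held-out patients by label propagation.  Fitting also
records per-split results (scores, selected features, predictions,
accuracy) the way the turnkey predictor loop reports them.

:class:`SparseGeneticClassifier` runs the rare-variant workflow: binary
pathway co-mutation networks, an optional permutation-based label-enrichment
filter, cumulative feature scores across folds, and a cutoff-sweep ROC built
from the pathway-membership classification rule.

:class:`MutationSmoother` is the transformer wrapping random-walk-with-
restart mutation smoothing and binarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .dataset import (
    PatientDataset,
    PredictorConfig,
    ValidationError,
    resample_training,
    split_train_test,
    validate_dataset,
    TRAIN,
    TEST,
)
from .evaluation import perf_calc_from_counts
from .feature_selection import (
    call_feature_selection,
    cumulative_scores,
    label_enrichment,
    score_features_one_split,
)
from .integration import QueryContext, solve_network_weights
from .prediction import classify_by_propagation, sparse_pathway_classify
from .similarity import (
    SimilarityNetwork,
    SparsifyParams,
    binary_pathway_network,
    build_feature_networks,
)
from .smoothing import SmoothingParams, binarize_smoothed, rwr_smooth

__all__ = [
    "SplitRecord",
    "PredictorResult",
    "SparseResult",
    "PSNClassifier",
    "SparseGeneticClassifier",
    "MutationSmoother",
]


@dataclass
class SplitRecord:
    """Everything recorded for one train/test split."""

    seed: int
    assignment: dict[str, str]
    feature_scores: dict[str, dict[str, int]]  # class -> feature -> score
    feature_selected: dict[str, list[str]]  # class -> features used for test
    predictions: pd.DataFrame
    accuracy: float


@dataclass
class PredictorResult:
    input_networks: list[str]
    splits: list[SplitRecord]
    config: PredictorConfig
    seeds: list[int]

    def score_table(self, class_label: str) -> pd.DataFrame:
        """Feature x split table of scores for one class (NaN = unscored)."""
        cols = {}
        for k, rec in enumerate(self.splits, 1):
            cols[f"Split{k}"] = rec.feature_scores.get(class_label, {})
        return pd.DataFrame(cols).reindex(sorted(self.input_networks))

    @property
    def accuracies(self) -> list[float]:
        return [rec.accuracy for rec in self.splits]


@dataclass
class SparseResult:
    cumulative_scores: dict[str, int]
    per_split_scores: list[dict[str, int]]
    enrichment: list[dict]
    performance: pd.DataFrame
    auc: float
    prauc: float
    selected_by_cutoff: dict[int, list[str]]


def _derive_seed(random_state: int, k: int) -> int:
    return (int(random_state) * 100_003 + 7919 * k) % (2**31 - 1)


class PSNClassifier(ClassifierMixin, BaseEstimator):
    """Patient classification through similarity-network integration.

    Parameters
    ----------
    rules : mapping layer -> {feature -> [measure, ...]}
        Grouping of each layer's measures into features (one PSN each).
    metrics : mapping layer -> str or callable
        Similarity metric per layer (``pearson``, ``normdiff``,
        ``scaled_euclidean``, ``binary`` or a custom network builder).
    num_splits, feat_score_max, feat_sel_cutoff, train_fraction, resampling
        The feature-scoring loop settings (see :class:`PredictorConfig`).
    fs_pct_pass : float
        Consensus fraction of splits a feature must reach
        ``feat_sel_cutoff`` in to enter the final model used by ``predict``.
    ridge : float
        Regularization strength of the network-weight fit.
    lam : float
        Smoothing strength of the label-propagation system (I + lam L).
    sparsify : SparsifyParams or None
        Optional edge filtering applied to every built network.

    Attributes
    ----------
    classes_ : ndarray of class labels
    result_ : PredictorResult with one record per train/test split
    feature_scores_ : class -> feature x split score table
    selected_features_ : class -> consensus feature list (for predict)
    train_dataset_ : the dataset the model was fitted on
    """

    def __init__(
        self,
        rules=None,
        metrics=None,
        num_splits: int = 10,
        feat_score_max: int = 10,
        feat_sel_cutoff: int = 9,
        train_fraction: float = 0.8,
        resampling: str = "holdout",
        montecarlo_fraction: float = 0.8,
        fs_pct_pass: float = 0.7,
        ridge: float = 1.0,
        lam: float = 1.0,
        sparsify: SparsifyParams | None = None,
        min_carriers: int = 6,
        random_state: int = 0,
    ):
        self.rules = rules
        self.metrics = metrics
        self.num_splits = num_splits
        self.feat_score_max = feat_score_max
        self.feat_sel_cutoff = feat_sel_cutoff
        self.train_fraction = train_fraction
        self.resampling = resampling
        self.montecarlo_fraction = montecarlo_fraction
        self.fs_pct_pass = fs_pct_pass
        self.ridge = ridge
        self.lam = lam
        self.sparsify = sparsify
        self.min_carriers = min_carriers
        self.random_state = random_state

    def _config(self) -> PredictorConfig:
        return PredictorConfig(
            num_splits=self.num_splits,
            feat_score_max=self.feat_score_max,
            feat_sel_cutoff=self.feat_sel_cutoff,
            train_fraction=self.train_fraction,
            resampling_scheme=self.resampling,
            montecarlo_fraction=self.montecarlo_fraction,
            rng_seed=self.random_state,
        )

    def fit(self, X: PatientDataset, y=None) -> "PSNClassifier":
        """Run the full scoring/classification loop on a labelled dataset.

        ``X`` is a :class:`PatientDataset`; ``y`` may override its labels
        (a mapping or a sequence aligned with ``X.ids``).
        """
        if self.rules is None or self.metrics is None:
            raise ValidationError("rules and metrics must be provided", field="rules")
        ds = X
        if y is not None:
            labels = dict(y) if isinstance(y, Mapping) else dict(zip(X.ids, y))
            ds = PatientDataset(ids=list(X.ids), labels=labels, assays=X.assays)
        validate_dataset(ds, self.rules, raise_on_error=True)
        cfg = self._config()
        self.classes_ = np.array(ds.classes)
        inventory = sorted(
            f for groups in self.rules.values() for f in groups
        )

        records: list[SplitRecord] = []
        seeds: list[int] = []
        for k in range(cfg.num_splits):
            seed_k = _derive_seed(self.random_state, k)
            seeds.append(seed_k)
            records.append(self._run_split(ds, cfg, seed_k))

        self.result_ = PredictorResult(
            input_networks=inventory, splits=records, config=cfg, seeds=seeds
        )
        self.feature_scores_ = {
            cls: self.result_.score_table(cls) for cls in ds.classes
        }
        self.selected_features_ = {}
        for cls in ds.classes:
            consensus = call_feature_selection(
                self.feature_scores_[cls], self.feat_sel_cutoff, self.fs_pct_pass
            )
            if not consensus:
                consensus = [self._best_feature(self.feature_scores_[cls], cls)]
            self.selected_features_[cls] = consensus
        self.train_dataset_ = ds
        return self

    @staticmethod
    def _best_feature(tbl: pd.DataFrame, cls: str) -> str:
        totals = tbl.fillna(0).sum(axis=1).sort_values(ascending=False)
        best = str(totals.index[0])
        warnings.warn(
            f"class {cls!r}: no feature passed the cutoff; falling back to the "
            f"best-scoring feature {best!r}"
        )
        return best

    def _run_split(self, ds: PatientDataset, cfg: PredictorConfig,
                   seed: int) -> SplitRecord:
        assignment = split_train_test(ds, cfg, seed)
        train_ids = [i for i in ds.labelled_ids() if assignment[i] == TRAIN]
        test_ids = [i for i in ds.labelled_ids() if assignment[i] == TEST]
        train_ds = ds.subset(train_ids)
        train_nets = build_feature_networks(
            train_ds, self.rules, self.metrics, restrict_to=train_ids,
            sparsify=self.sparsify, min_carriers=self.min_carriers,
        )
        feature_scores: dict[str, dict[str, int]] = {}
        selected: dict[str, list[str]] = {}
        for cls in ds.classes:
            scores = score_features_one_split(
                train_ds, self.rules, self.metrics, cls, cfg, seed,
                networks=train_nets, ridge=self.ridge,
            )
            feature_scores[cls] = scores
            chosen = sorted(
                nm for nm, s in scores.items() if s >= cfg.feat_sel_cutoff
            )
            if not chosen:
                best = max(sorted(scores), key=lambda nm: scores[nm])
                warnings.warn(
                    f"split seed {seed}: class {cls!r} has no feature scoring "
                    f">= {cfg.feat_sel_cutoff}; using best-scoring {best!r}"
                )
                chosen = [best]
            selected[cls] = chosen
        train_labels = {i: ds.labels[i] for i in train_ids}
        predictions = classify_by_propagation(
            ds, self.rules, self.metrics, selected, train_labels, test_ids,
            lam=self.lam,
        )
        accuracy = float((predictions["PRED_CLASS"] == predictions["STATUS"]).mean())
        return SplitRecord(seed, assignment, feature_scores, selected,
                           predictions, accuracy)

    def predict(self, X: PatientDataset) -> np.ndarray:
        """Classify new patients against the fitted cohort."""
        return self.predict_table(X)["PRED_CLASS"].to_numpy()

    def predict_table(self, X: PatientDataset) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selected_features_")
        merged = PatientDataset.merge(self.train_dataset_, X)
        return classify_by_propagation(
            merged, self.rules, self.metrics, self.selected_features_,
            dict(self.train_dataset_.labels), list(X.ids), lam=self.lam,
        )


class SparseGeneticClassifier(BaseEstimator):
    """Case/control classification from sparse genetic events.

    Feature selection runs over ``num_splits`` folds, each training on the
    complementary ``(num_splits - 1)/num_splits`` of the cohort.  Within a
    fold, pathway co-mutation networks (carrier floor ``min_carriers``) are
    optionally filtered by label enrichment and then scored 0..
    ``feat_score_max`` by integration queries for the predicted class.
    Scores accumulate across folds up to ``num_splits * feat_score_max``;
    sweeping a cutoff over cumulative scores yields the ROC.
    """

    def __init__(
        self,
        gene_sets=None,
        predict_class: str = "case",
        num_splits: int = 3,
        feat_score_max: int = 3,
        enrich_labels: bool = True,
        num_perms: int = 50,
        enrich_threshold: float = 0.07,
        min_carriers: int = 6,
        resampling: str = "holdout",
        montecarlo_fraction: float = 0.8,
        ridge: float = 1.0,
        random_state: int = 0,
    ):
        self.gene_sets = gene_sets
        self.predict_class = predict_class
        self.num_splits = num_splits
        self.feat_score_max = feat_score_max
        self.enrich_labels = enrich_labels
        self.num_perms = num_perms
        self.enrich_threshold = enrich_threshold
        self.min_carriers = min_carriers
        self.resampling = resampling
        self.montecarlo_fraction = montecarlo_fraction
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X: Mapping[str, set], y: Mapping[str, str]) -> "SparseGeneticClassifier":
        """``X``: patient -> mutated gene symbols; ``y``: patient -> label."""
        if self.gene_sets is None:
            raise ValidationError("gene_sets must be provided", field="gene_sets")
        sets = (self.gene_sets.as_dict()
                if hasattr(self.gene_sets, "as_dict") else dict(self.gene_sets))
        labels = dict(y)
        if self.predict_class not in set(labels.values()):
            raise ValidationError(
                f"predict_class {self.predict_class!r} absent from labels",
                field="predict_class",
            )
        events = {str(p): set(X.get(p, ())) for p in labels}
        cohort = sorted(labels)
        folds = self._stratified_folds(cohort, labels)

        per_split: list[dict[str, int]] = []
        enrich_records: list[dict] = []
        for k, heldout in enumerate(folds):
            train = [p for p in cohort if p not in heldout]
            seed_k = _derive_seed(self.random_state, k)
            scores, enr = self._score_fold(events, sets, labels, train, seed_k)
            per_split.append(scores)
            enrich_records.append(enr)

        cum = cumulative_scores(per_split)
        max_score = self.num_splits * self.feat_score_max
        selected_by_cutoff = {
            c: sorted(nm for nm, s in cum.items() if s >= c)
            for c in range(1, max_score + 1)
        }
        perf = sparse_pathway_classify(
            events, selected_by_cutoff, sets, labels, self.predict_class
        )
        stats = perf_calc_from_counts(perf)

        self.cumulative_scores_ = cum
        self.per_split_scores_ = per_split
        self.enrichment_ = enrich_records
        self.performance_ = stats["rows"]
        self.auc_ = stats["auc"]
        self.prauc_ = stats["prauc"]
        self.selected_by_cutoff_ = selected_by_cutoff
        self.result_ = SparseResult(cum, per_split, enrich_records,
                                    stats["rows"], self.auc_, self.prauc_,
                                    selected_by_cutoff)
        return self

    def _stratified_folds(self, cohort: list[str],
                          labels: Mapping[str, str]) -> list[set[str]]:
        rng = np.random.default_rng(_derive_seed(self.random_state, 999))
        folds: list[set[str]] = [set() for _ in range(self.num_splits)]
        for cls in sorted(set(labels.values())):
            members = [p for p in cohort if labels[p] == cls]
            order = rng.permutation(len(members))
            for pos, idx in enumerate(order):
                folds[pos % self.num_splits].add(members[idx])
        return folds

    def _score_fold(self, events, sets, labels, train, seed):
        train_events = {p: events[p] for p in train}
        nets: dict[str, SimilarityNetwork] = {}
        for nm, genes in sets.items():
            net = binary_pathway_network(train_events, genes, nm,
                                         self.min_carriers)
            if net is not None:
                nets[nm] = net
        enr_record: dict = {}
        if self.enrich_labels and nets:
            train_labels = {p: labels[p] for p in train}
            enr = label_enrichment(
                nets, train_labels, self.predict_class,
                num_perms=self.num_perms, threshold=self.enrich_threshold,
                seed=seed,
            )
            enr_record = {nm: r for nm, r in enr.items()}
            nets = {nm: nets[nm] for nm, r in enr.items() if r.passed}
            if not nets:
                raise ValidationError(
                    "label enrichment eliminated every network; lower the "
                    "threshold or increase num_perms",
                    field="enrich_threshold",
                )
        scores = {nm: 0 for nm in nets}
        if not nets:
            return scores, enr_record
        class_train = [p for p in train if labels[p] == self.predict_class]
        background = [p for p in train if labels[p] != self.predict_class]
        for it in range(1, self.feat_score_max + 1):
            query = resample_training(
                class_train, self.resampling, self.feat_score_max, it, seed,
                self.montecarlo_fraction,
            )
            ctx = QueryContext(list(query), list(background), dict(nets))
            try:
                fit = solve_network_weights(ctx, ridge=self.ridge)
            except ValidationError:
                continue  # uninformative query in this fold: no scores added
            for nm in fit.positive():
                scores[nm] += 1
        return scores, enr_record

    def predict(self, X: Mapping[str, set], cutoff: int | None = None) -> pd.Series:
        """Case/control call per patient at a cumulative-score cutoff
        (default: half the maximum attainable score)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "cumulative_scores_")
        if cutoff is None:
            cutoff = max(1, (self.num_splits * self.feat_score_max) // 2)
        sets = (self.gene_sets.as_dict()
                if hasattr(self.gene_sets, "as_dict") else dict(self.gene_sets))
        selected = self.selected_by_cutoff_.get(cutoff, [])
        sel_genes = [set(sets[nm]) for nm in selected if nm in sets]
        out = {}
        for p, genes in X.items():
            is_case = any(set(genes) & gs for gs in sel_genes)
            out[str(p)] = self.predict_class if is_case else f"not_{self.predict_class}"
        return pd.Series(out)


class MutationSmoother(TransformerMixin, BaseEstimator):
    """RWR smoothing of binary mutation matrices over a gene network.

    ``transform`` returns the binarized (direct + inferred) mutation matrix
    when ``binarize=True`` (default), else the continuous smoothed scores.
    """

    def __init__(
        self,
        interaction_network: pd.DataFrame | None = None,
        restart: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
        binarize: bool = True,
        binarize_fraction: float = 0.03,
    ):
        self.interaction_network = interaction_network
        self.restart = restart
        self.tol = tol
        self.max_iter = max_iter
        self.binarize = binarize
        self.binarize_fraction = binarize_fraction

    def _params(self) -> SmoothingParams:
        return SmoothingParams(
            restart=self.restart, tol=self.tol, max_iter=self.max_iter,
            binarize_fraction=self.binarize_fraction,
        )

    def fit(self, X=None, y=None) -> "MutationSmoother":
        if self.interaction_network is None:
            raise ValidationError("interaction_network must be provided",
                                  field="interaction_network")
        self.genes_ = list(self.interaction_network.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "genes_")
        smoothed = rwr_smooth(X, self.interaction_network, self._params())
        if not self.binarize:
            return smoothed
        return binarize_smoothed(smoothed, X, self.binarize_fraction)
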