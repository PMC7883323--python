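"""Turnkey predictor loops: thin functional wrappers over the estimators."""

from __future__ import annotations

from typing import Mapping

from .dataset import PatientDataset, PredictorConfig
from .estimators import (
    PredictorResult,
    PSNClassifier,
    SparseGeneticClassifier,
    SparseResult,
)

__all__ = ["build_predictor", "build_predictor_sparse"]


def build_predictor(
    ds: PatientDataset,
    rules,
    metric_assignment,
    cfg: PredictorConfig,
    seed: int | None = None,
    **kwargs,
) -> PredictorResult:
    """Run the dense workflow and return the per-split results bundle."""
    clf = PSNClassifier(
        rules=rules,
        metrics=metric_assignment,
        num_splits=cfg.num_splits,
        feat_score_max=cfg.feat_score_max,
        feat_sel_cutoff=cfg.feat_sel_cutoff,
        train_fraction=cfg.train_fraction,
        resampling=cfg.resampling_scheme,
        montecarlo_fraction=cfg.montecarlo_fraction,
        random_state=cfg.rng_seed if seed is None else seed,
        **kwargs,
    )
    clf.fit(ds)
    return clf.result_


def build_predictor_sparse(
    labels: Mapping[str, str],
    events: Mapping[str, set],
    sets,
    cfg: PredictorConfig,
    predict_class: str = "case",
    enrich: bool = True,
    num_perms: int = 50,
    enrich_threshold: float = 0.07,
    seed: int | None = None,
    **kwargs,
) -> SparseResult:
    """Run the sparse genetic workflow and return its results bundle."""
    clf = SparseGeneticClassifier(
        gene_sets=sets,
        predict_class=predict_class,
        num_splits=cfg.num_splits,
        feat_score_max=cfg.feat_score_max,
        enrich_labels=enrich,
        num_perms=num_perms,
        enrich_threshold=enrich_threshold,
        resampling=cfg.resampling_scheme,
        montecarlo_fraction=cfg.montecarlo_fraction,
        random_state=cfg.rng_seed if seed is None else seed,
        **kwargs,
    )
    clf.fit(events, labels)
    return clf.result_
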