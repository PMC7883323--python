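"""Performance metrics: accuracy, confusion matrices, ROC/PR curves.

Score-based curves (dense workflow) are computed with scikit-learn
(trapezoidal AUROC; step-interpolated area under the precision–recall
curve).  The sparse workflow instead produces a table of confusion counts
at successive score cutoffs; ``perf_calc_from_counts`` turns such a table
into ROC/PR curves and areas directly from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .dataset import ValidationError
from .prediction import SCORE_SUFFIX

__all__ = [
    "CurveSummary",
    "EvaluationResult",
    "evaluate_predictions",
    "perf_calc_from_counts",
    "confusion_matrix_table",
]


@dataclass
class CurveSummary:
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auroc: float
    aupr: float


@dataclass
class EvaluationResult:
    accuracies: list[float]
    confusion_matrices: list[pd.DataFrame]
    curves: list[CurveSummary | None]
    mean_curve: CurveSummary | None
    excluded_splits: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_auroc(self) -> float | None:
        vals = [c.auroc for c in self.curves if c is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_aupr(self) -> float | None:
        vals = [c.aupr for c in self.curves if c is not None]
        return float(np.mean(vals)) if vals else None


def confusion_matrix_table(table: pd.DataFrame) -> pd.DataFrame:
    """True class (rows) x predicted class (columns) counts."""
    return pd.crosstab(table["STATUS"], table["PRED_CLASS"], dropna=False)


def evaluate_predictions(
    tables: Sequence[pd.DataFrame],
    positive_class: str,
) -> EvaluationResult:
    """Per-split accuracy, confusion matrices and ROC/PR curves.

    ROC and PR are computed by sweeping the positive class's score column.
    Splits whose test set contains a single truth class have no defined ROC
    and are excluded from the curve averages (their index is recorded).
    The mean curve is the vertical average of the per-split curves on a
    common grid.
    """
    if not tables:
        raise ValidationError("need at least one prediction table", field="tables")
    col = positive_class + SCORE_SUFFIX
    accs, cms, curves, excluded = [], [], [], []
    for k, t in enumerate(tables):
        if col not in t.columns:
            raise ValidationError(f"missing score column {col!r}", field=col)
        accs.append(float((t["PRED_CLASS"] == t["STATUS"]).mean()))
        cms.append(confusion_matrix_table(t))
        y = (t["STATUS"] == positive_class).to_numpy()
        s = t[col].to_numpy(dtype=float)
        if y.all() or not y.any():
            excluded.append(k)
            curves.append(None)
            continue
        fpr, tpr, _ = roc_curve(y, s)
        prec, rec, _ = precision_recall_curve(y, s)
        curves.append(
            CurveSummary(
                fpr=fpr,
                tpr=tpr,
                recall=rec[::-1],
                precision=prec[::-1],
                auroc=float(auc(fpr, tpr)),
                aupr=float(average_precision_score(y, s)),
            )
        )
    mean_curve = _vertical_average([c for c in curves if c is not None])
    return EvaluationResult(accs, cms, curves, mean_curve, excluded)


def _vertical_average(curves: list[CurveSummary]) -> CurveSummary | None:
    if not curves:
        return None
    grid = np.linspace(0.0, 1.0, 101)
    tprs = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    precs = np.vstack([np.interp(grid, c.recall, c.precision) for c in curves])
    return CurveSummary(
        fpr=grid,
        tpr=tprs.mean(axis=0),
        recall=grid,
        precision=precs.mean(axis=0),
        auroc=float(np.mean([c.auroc for c in curves])),
        aupr=float(np.mean([c.aupr for c in curves])),
    )


def perf_calc_from_counts(tbl: pd.DataFrame) -> dict:
    """ROC/PR areas from a table of (score, tp, fp, tn, fn) rows.

    The positive and negative marginals (tp+fn, fp+tn) must be constant
    across rows.  TPR = tp/(tp+fn), FPR = fp/(fp+tn), precision = tp/(tp+fp)
    (defined as 1 when tp+fp = 0).  The ROC curve is anchored at (0,0) and
    (1,1) and integrated by trapezoids; the PR curve uses step
    interpolation.
    """
    req = {"tp", "fp", "tn", "fn"}
    if not req <= set(tbl.columns):
        raise ValidationError("table must have tp, fp, tn, fn columns", field="tbl")
    tp = tbl["tp"].to_numpy(float)
    fp = tbl["fp"].to_numpy(float)
    tn = tbl["tn"].to_numpy(float)
    fn = tbl["fn"].to_numpy(float)
    if (tp < 0).any() or (fp < 0).any() or (tn < 0).any() or (fn < 0).any():
        raise ValidationError("counts must be non-negative", field="tbl")
    n_pos = tp + fn
    n_neg = fp + tn
    if len(set(n_pos)) != 1 or len(set(n_neg)) != 1:
        raise ValidationError(
            "tp+fn and fp+tn must be constant across rows", field="tbl"
        )
    if n_pos[0] == 0 or n_neg[0] == 0:
        raise ValidationError("need at least one positive and one negative",
                              field="tbl")
    tpr = tp / n_pos
    fpr = fp / n_neg
    with np.errstate(invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 1.0)

    order = np.argsort(fpr, kind="stable")
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], tpr[order], [1.0]])
    roc_auc = float(np.trapezoid(fy, fx))

    # PR: walk recall from 0 upward, precision held as a step function
    r_order = np.argsort(tpr, kind="stable")
    rec = np.concatenate([[0.0], tpr[r_order]])
    pre = np.concatenate([[1.0], prec[r_order]])
    pr_auc = float(np.sum(np.diff(rec) * pre[1:]))

    rows = tbl.copy()
    rows["tpr"] = tpr
    rows["fpr"] = fpr
    rows["precision"] = prec
    return {"auc": roc_auc, "prauc": pr_auc, "rows": rows}
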