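"""Network-based smoothing of sparse somatic mutation profiles.

Binary mutation profiles are desparsified by propagating each patient's
mutations over a binary, symmetric gene–gene interaction network with a
random walk with restart (RWR): starting from the patient's normalized
mutation vector ``F0``, iterate

    F <- (1 - restart) * W @ F + restart * F0

where ``W`` is the column-normalized adjacency (isolated genes keep their
own mass through a self-loop).  ``W`` is column-stochastic, so each
patient's score mass stays 1 throughout and converged scores lie in [0, 1]:
a gene's score reflects its network proximity to the patient's mutations.
The smoothed profile is then re-binarized by ranking and keeping the
top-scoring fraction of genes (default 3%), always unioned with the
patient's directly observed mutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ValidationError

__all__ = ["SmoothingParams", "rwr_smooth", "binarize_smoothed"]


@dataclass
class SmoothingParams:
    restart: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    binarize_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValidationError("restart must be in (0, 1]", field="restart")
        if self.tol <= 0:
            raise ValidationError("tol must be positive", field="tol")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1", field="max_iter")
        if not (0.0 < self.binarize_fraction <= 1.0):
            raise ValidationError(
                "binarize_fraction must be in (0, 1]", field="binarize_fraction"
            )


def _check_interaction_network(net: pd.DataFrame) -> None:
    if net.shape[0] != net.shape[1] or list(net.index) != list(net.columns):
        raise ValidationError(
            "interaction network must be square with matching gene names",
            field="net",
        )
    A = net.to_numpy(dtype=float)
    if not np.array_equal(A, A.T):
        raise ValidationError("interaction network must be symmetric", field="net")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValidationError("interaction network must be binary", field="net")


def rwr_smooth(
    geno: pd.DataFrame,
    net: pd.DataFrame,
    p: SmoothingParams | None = None,
) -> pd.DataFrame:
    """Random-walk-with-restart smoothing of a binary mutation matrix.

    ``geno`` is gene x patient with 0/1 entries; its genes must all appear
    in the interaction network.  Returns a gene x patient matrix over the
    network's genes with per-patient scores summing to 1.  Patients with no
    mutations pass through as all-zero columns with a warning.
    """
    p = p or SmoothingParams()
    _check_interaction_network(net)
    vals = geno.fillna(0).to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValidationError("mutation matrix must be binary", field="geno")
    unknown = [g for g in geno.index if g not in net.index]
    if unknown:
        raise ValidationError(
            f"genes absent from the interaction network: {unknown[:5]}",
            field="geno",
        )

    genes = list(net.index)
    A = net.to_numpy(dtype=float)
    colsum = A.sum(axis=0)
    W = np.divide(A, colsum, out=np.zeros_like(A), where=colsum > 0)
    isolated = colsum == 0
    if isolated.any():  # isolated seeded gene keeps its mass
        W[isolated, isolated] = 1.0

    F0 = pd.DataFrame(0.0, index=genes, columns=geno.columns)
    F0.loc[geno.index] = vals
    mass = F0.sum(axis=0).to_numpy()
    empty = mass == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} patient(s) have no mutations; passed through "
            "as all-zero"
        )
    F0v = F0.to_numpy() / np.where(empty, 1.0, mass)

    F = F0v.copy()
    r = p.restart
    for _ in range(p.max_iter):
        F_next = (1.0 - r) * (W @ F) + r * F0v
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < p.tol:
            break
    else:
        warnings.warn(
            f"RWR did not reach tol={p.tol} within {p.max_iter} iterations "
            f"(last delta {delta:.3g})"
        )
    return pd.DataFrame(F, index=genes, columns=geno.columns)


def binarize_smoothed(
    smoothed: pd.DataFrame,
    original: pd.DataFrame,
    fraction: float = 0.03,
) -> pd.DataFrame:
    """Rank-and-threshold a smoothed matrix back to binary.

    Per patient, the ``ceil(fraction * n_genes)`` genes with the highest
    positive smoothed scores are set to 1 (ties at the cutoff broken by
    gene-name order); the patient's original mutations are always retained,
    so the result is never sparser than the input — the classifier then
    works with direct and inferred mutations together.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]", field="fraction")
    if list(smoothed.columns) != list(original.columns):
        raise ValidationError("patient columns must match", field="original")
    orig = original.reindex(index=smoothed.index, fill_value=0).fillna(0)
    n_genes = smoothed.shape[0]
    k = math.ceil(fraction * n_genes)
    out = pd.DataFrame(0, index=smoothed.index, columns=smoothed.columns, dtype=int)
    for pat in smoothed.columns:
        col = smoothed[pat]
        candidates = sorted(
            (float(-col[g]), str(g)) for g in smoothed.index if col[g] > 0
        )
        for _, g in candidates[:k]:
            out.loc[g, pat] = 1
    return (out | (orig.astype(int) > 0).astype(int)).astype(int)
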