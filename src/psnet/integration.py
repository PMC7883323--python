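"""Regularized network integration and label propagation.

The integration step follows the GeneMANIA-style recipe: a *query* (the
training patients of one class, or a subsample of them) and a *background*
(training patients of the other classes) define a pairwise regression target
— +1 for query–query pairs, -1 for query–background pairs, with
background–background pairs excluded.  Candidate network edge weights are the
regressors; a ridge-regularized least-squares fit, followed by iterative
clipping of negative coefficients, yields one non-negative weight per
network.  Networks earning a positive weight are "useful" for discriminating
the query class and have their feature score incremented by the caller.

Label propagation scores every patient in an integrated network by solving
the graph-regularized linear system ``(I + lam * L) f = y`` with ``L`` the
combinatorial Laplacian and ``y`` the 0/1 training-label prior — the Gaussian
random field / regularized Laplacian formulation of semi-supervised learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dataset import ValidationError
from .similarity import SimilarityNetwork

__all__ = [
    "QueryContext",
    "NetworkWeights",
    "PropagationScores",
    "build_target_comembership",
    "solve_network_weights",
    "combine_networks",
    "propagate_labels",
]


@dataclass
class QueryContext:
    query_ids: list[str]
    background_ids: list[str]
    candidate_networks: dict[str, SimilarityNetwork]

    def __post_init__(self) -> None:
        overlap = set(self.query_ids) & set(self.background_ids)
        if overlap:
            raise ValidationError(
                f"query and background overlap: {sorted(overlap)[:5]}",
                field="query_ids",
            )
        if not self.query_ids or not self.background_ids:
            raise ValidationError(
                "query and background must both be non-empty", field="query_ids"
            )


@dataclass
class NetworkWeights:
    weights: dict[str, float]
    residual_norm: float

    def positive(self) -> list[str]:
        return [k for k, w in self.weights.items() if w > 0]


@dataclass
class PropagationScores:
    scores: dict[str, float]
    iterations: int
    residual: float


def build_target_comembership(
    query_ids: Sequence[str], background_ids: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Pairwise regression target: +1 within the query, -1 across.

    Background–background pairs are excluded — only same-class-as-query
    versus different-class information enters the fit.
    """
    q = list(dict.fromkeys(query_ids))
    b = list(dict.fromkeys(background_ids))
    if set(q) & set(b):
        raise ValidationError("query and background overlap", field="query_ids")
    if not q or not b:
        raise ValidationError("both sets must be non-empty", field="query_ids")
    target: dict[tuple[str, str], float] = {}
    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            a, c = (q[i], q[j]) if q[i] <= q[j] else (q[j], q[i])
            target[(a, c)] = 1.0
    for qi in q:
        for bi in b:
            a, c = (qi, bi) if qi <= bi else (bi, qi)
            target[(a, c)] = -1.0
    return target


def solve_network_weights(ctx: QueryContext, ridge: float = 1.0) -> NetworkWeights:
    """Non-negative ridge weights for the candidate networks.

    Solves ``min ||X w - y||^2 + lam ||w||^2`` over the comembership pairs,
    where column k of X holds network k's edge weights on those pairs (absent
    edge = 0).  The penalty is ``ridge`` scaled by the mean diagonal of
    ``X'X`` so the fit is equivariant under a common rescaling of all
    networks.  Negative coefficients are clipped to zero and the system is
    re-solved on the surviving networks until all weights are non-negative.
    Deterministic.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    target = build_target_comembership(ctx.query_ids, ctx.background_ids)
    pairs = list(target)
    y = np.array([target[p] for p in pairs])
    names = list(ctx.candidate_networks)
    if not names:
        raise ValidationError("no candidate networks", field="candidate_networks")

    index = {pid: k for k, pid in enumerate(ctx.query_ids + ctx.background_ids)}
    rows = np.array([index[a] for a, _ in pairs])
    cols = np.array([index[b] for _, b in pairs])
    X = np.empty((len(pairs), len(names)))
    for k, nm in enumerate(names):
        A = ctx.candidate_networks[nm].to_sparse(index)
        X[:, k] = np.asarray(A[rows, cols]).ravel()

    gram_diag = (X * X).sum(axis=0)
    if not np.any(gram_diag > 0):
        raise ValidationError(
            "uninformative query: no candidate network touches any fit pair",
            field="candidate_networks",
        )
    lam = ridge * float(gram_diag.mean())

    active = list(range(len(names)))
    w_active = np.zeros(0)
    while active:
        Xa = X[:, active]
        G = Xa.T @ Xa + lam * np.eye(len(active))
        w_active = np.linalg.solve(G, Xa.T @ y)
        neg = w_active < -1e-12
        if not neg.any():
            break
        active = [a for a, is_neg in zip(active, neg) if not is_neg]
    weights = {nm: 0.0 for nm in names}
    for a, w in zip(active, w_active):
        weights[names[a]] = max(float(w), 0.0)
    w_full = np.array([weights[nm] for nm in names])
    residual = float(np.linalg.norm(X @ w_full - y))
    return NetworkWeights(weights=weights, residual_norm=residual)


def combine_networks(
    weights: NetworkWeights | Mapping[str, float],
    networks: Mapping[str, SimilarityNetwork],
    name: str = "integrated",
) -> SimilarityNetwork:
    """Weighted sum of networks over the union of their node sets."""
    wmap = weights.weights if isinstance(weights, NetworkWeights) else dict(weights)
    missing = [nm for nm in networks if nm not in wmap]
    if missing:
        raise ValidationError(f"no weight for networks {missing[:5]}", field="weights")
    out = SimilarityNetwork(name)
    for nm, net in networks.items():
        out.nodes |= net.nodes
        w = wmap[nm]
        if w == 0:
            continue
        for e, ew in net.edges.items():
            out.edges[e] = out.edges.get(e, 0.0) + w * ew
    return out


def propagate_labels(
    net: SimilarityNetwork,
    prior: Mapping[str, float],
    lam: float = 1.0,
    tol: float = 1e-10,
) -> PropagationScores:
    """Solve ``(I + lam * L) f = prior`` on the network.

    The system is symmetric positive definite, so the solution is unique and
    obeys the maximum principle: every score lies between the smallest and
    largest prior value (up to solver tolerance).  Solved by conjugate
    gradients with a dense direct fallback.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    nodes = sorted(set(net.nodes) | set(prior))
    missing = [n for n in net.nodes if n not in prior]
    if missing:
        raise ValidationError(
            f"prior undefined for nodes {sorted(missing)[:5]}", field="prior"
        )
    index = {n: k for k, n in enumerate(nodes)}
    W = net.to_sparse(index)
    if W.nnz and not np.all(np.isfinite(W.data)):
        raise ValidationError("non-finite edge weights", field="edges")
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    A = (sp.eye(len(nodes)) + lam * L).tocsr()
    y = np.array([float(prior[n]) for n in nodes])

    iters = 0

    def _count(_):
        nonlocal iters
        iters += 1

    f, info = spla.cg(A, y, rtol=tol, atol=0.0, maxiter=10 * len(nodes) + 100,
                      callback=_count)
    if info != 0:  # pragma: no cover - CG on SPD systems converges
        f = spla.spsolve(A.tocsc(), y)
    residual = float(np.linalg.norm(A @ f - y))
    return PropagationScores(
        scores={n: float(f[index[n]]) for n in nodes},
        iterations=iters,
        residual=residual,
    )
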