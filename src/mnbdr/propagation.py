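"""Damped network propagation over the module network.

Disease module scores are refined by the PageRank-style iteration

    P_k = lam * W @ P_{k-1} + (1 - lam) * P0

where W is the column-normalized adjacency of the module network and P0
the raw importance prior.  Isolated modules get uniform teleport columns,
the standard dangling-node repair, so W stays column-stochastic and mass
is conserved every iteration.  Drug-side vectors are never propagated;
only the disease prior travels through the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crosstalk import ModuleNetwork
from .importance import ImportanceVector

__all__ = ["TransitionMatrix", "PropagationResult", "transition_matrix", "propagate",
           "rank_modules"]


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over a fixed module order."""

    matrix: np.ndarray
    module_order: list[str]

    def __post_init__(self) -> None:
        col_sums = self.matrix.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-12):
            raise ValueError("columns must sum to 1")


@dataclass
class PropagationResult:
    """Converged propagation scores with the prior and convergence info."""

    scores: pd.Series  # index: module order
    prior: pd.Series
    lam: float
    iterations: int
    residual: float


def transition_matrix(net: ModuleNetwork) -> TransitionMatrix:
    """Column normalization of the module network's unweighted adjacency.

    All-zero columns (modules with no cross-talk partner) are replaced by
    uniform columns 1/m.
    """
    order = net.module_names
    if not order:
        raise ValueError("module network has no nodes")
    m = len(order)
    idx = {name: i for i, name in enumerate(order)}
    adj = np.zeros((m, m))
    for a, b in net.graph.edges:
        adj[idx[a], idx[b]] = 1.0
        adj[idx[b], idx[a]] = 1.0
    col_sums = adj.sum(axis=0)
    dangling = col_sums == 0
    adj[:, dangling] = 1.0 / m
    col_sums = adj.sum(axis=0)
    return TransitionMatrix(matrix=adj / col_sums, module_order=order)


def propagate(
    w: TransitionMatrix,
    p0: ImportanceVector,
    lam: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PropagationResult:
    """Iterate P_k = lam*W*P_{k-1} + (1-lam)*P0 to convergence.

    P0 is L1-normalized internally, so the converged scores sum to 1 and
    the tolerance is scale-free; downstream consumers use only the ranking,
    which is invariant to this normalization.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lam must be in (0, 1)")
    prior = p0.values.reindex(w.module_order)
    if prior.isna().any():
        missing = prior[prior.isna()].index.tolist()
        raise ValueError(f"prior lacks scores for modules: {missing[:5]}")
    total = prior.sum()
    if total <= 0:
        raise ValueError("prior importance vector is all zero: nothing to propagate")
    v0 = prior.to_numpy() / total
    p = v0.copy()
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = lam * (w.matrix @ p) + (1.0 - lam) * v0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            break
    return PropagationResult(
        scores=pd.Series(p, index=w.module_order),
        prior=pd.Series(v0, index=w.module_order),
        lam=lam,
        iterations=iterations,
        residual=residual,
    )


def rank_modules(result: PropagationResult | pd.Series, top_n: int = 15) -> list[tuple[str, float]]:
    """Top modules by score, descending, ties broken by module name.

    Accepts either a propagation result or a bare score series (the latter
    supports the module-only variant that skips propagation).  Returns all
    modules if fewer than ``top_n`` exist.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scores = result.scores if isinstance(result, PropagationResult) else result
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:top_n]
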