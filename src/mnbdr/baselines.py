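"""Classic connectivity-map scores and the module-only ranking variant.

These serve as comparison baselines for the module-network method:

* ``ks_connectivity`` — the original CMap score: a signed two-sample
  Kolmogorov–Smirnov-style enrichment of the up and down tag lists in the
  drug's ranked gene list, combined as KS_up - KS_down (range [-2, 2]).
* ``zhang_score`` — signed-rank correlation of the signature with the
  drug profile, normalized to [-1, 1] by the maximal attainable sum.
* ``xsum_score`` — sum of drug values over the up tags minus the down
  tags after zeroing every gene outside the drug's extreme top/bottom k.
* ``module_rank_no_network`` — the module-only variant: disease modules
  ranked by raw importance, skipping propagation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneScoreVector, ModuleSet
from .importance import ImportanceVector, module_importance
from .propagation import rank_modules

__all__ = [
    "Signature",
    "make_signature",
    "ranked_gene_list",
    "ks_connectivity",
    "zhang_score",
    "xsum_score",
    "module_rank_no_network",
]


@dataclass(frozen=True)
class Signature:
    """Up/down tag lists derived from a disease score vector."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down tags must be disjoint")


def make_signature(scores: GeneScoreVector, k: int = 100) -> Signature:
    """Top-k most up- and down-perturbed genes of a condition.

    Only genes with strictly positive (negative) scores enter the up
    (down) list, so a one-sided vector yields a one-sided signature.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = scores.scores
    up = tuple(s[s > 0].sort_values(ascending=False, kind="stable").index[:k])
    down = tuple(s[s < 0].sort_values(ascending=True, kind="stable").index[:k])
    return Signature(up=up, down=down)


def ranked_gene_list(scores: GeneScoreVector) -> list[str]:
    """Genes ordered by score descending (ties broken by gene id)."""
    s = scores.scores
    return sorted(s.index, key=lambda g: (-s[g], g))


def _ks_statistic(tags: tuple[str, ...], ranked: list[str]) -> float:
    """One tag-list KS enrichment against a ranked list of n genes."""
    n = len(ranked)
    t = len(tags)
    if t == 0:
        return 0.0
    pos = {g: i + 1 for i, g in enumerate(ranked)}
    missing = [g for g in tags if g not in pos]
    if missing:
        raise ValueError(f"signature genes missing from ranked list: {missing[:5]}")
    v = np.sort(np.array([pos[g] for g in tags], dtype=float))
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a > b else -b)


def ks_connectivity(sig: Signature, drug_ranked_genes: list[str]) -> float:
    """CMap connectivity score KS_up - KS_down; 0 when the two KS agree."""
    ks_up = _ks_statistic(sig.up, drug_ranked_genes) if sig.up else 0.0
    ks_down = _ks_statistic(sig.down, drug_ranked_genes) if sig.down else 0.0
    return ks_up - ks_down


def zhang_score(sig: Signature, drug_scores: GeneScoreVector) -> float:
    """Zhang connection strength in [-1, 1].

    Drug genes get signed ranks: magnitude = rank of |value| ascending
    (the most extreme gene has magnitude n), sign from the value.  The
    score is the sum of signature sign x drug signed rank over signature
    genes, divided by the maximal attainable sum (signature genes sitting
    at the n most extreme ranks with matching signs).
    """
    s = drug_scores.scores
    tags = list(sig.up) + list(sig.down)
    missing = [g for g in tags if g not in s.index]
    if missing:
        raise ValueError(f"signature genes missing from drug profile: {missing[:5]}")
    order = sorted(s.index, key=lambda g: (abs(s[g]), g))  # least extreme first
    magnitude = {g: i + 1 for i, g in enumerate(order)}
    n = len(order)
    t = len(tags)
    if t == 0:
        return 0.0
    signs = {g: 1.0 for g in sig.up} | {g: -1.0 for g in sig.down}
    total = sum(signs[g] * np.sign(s[g]) * magnitude[g] for g in tags)
    max_sum = sum(range(n - t + 1, n + 1))
    return float(total / max_sum)


def xsum_score(sig: Signature, drug_scores: GeneScoreVector, extreme_k: int = 100) -> float:
    """Extreme-sum score: truncate the drug profile to its top/bottom k
    genes by value, then sum over up tags minus down tags."""
    if extreme_k < 1:
        raise ValueError("extreme_k must be >= 1")
    s = drug_scores.scores
    order = sorted(s.index, key=lambda g: (-s[g], g))
    keep = set(order[:extreme_k]) | set(order[-extreme_k:])
    truncated = s.where(s.index.isin(keep), 0.0)
    up_sum = float(truncated.reindex(list(sig.up)).fillna(0.0).sum())
    down_sum = float(truncated.reindex(list(sig.down)).fillna(0.0).sum())
    return up_sum - down_sum


def module_rank_no_network(
    disease_scores: GeneScoreVector, modules: ModuleSet, top_n: int = 15
) -> list[tuple[str, float]]:
    """Disease module ranking by raw importance, without propagation.

    The module-only baseline: identical to the full pipeline except the
    network-propagation refinement is replaced by the identity.
    """
    imp = module_importance(disease_scores, modules)
    return rank_modules(imp.values, top_n=top_n)
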