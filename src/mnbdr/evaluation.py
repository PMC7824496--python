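"""Evaluation of ranked drug lists against a benchmark standard.

Per-disease ROC AUC and the unnormalized partial AUC restricted to
FPR <= 0.1 (range [0, 0.1]; chance level 0.005), averaged across diseases,
with permutation p-values obtained by reassigning each disease's positive
labels uniformly at random among its candidate drugs.  Both the empirical
(+1 pseudo-count) and a Gaussian-approximation tail p are reported: with
10^4 draws the empirical p is floored at ~10^-4, so extreme significance
can only be expressed parametrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .io import BenchmarkStandard

__all__ = [
    "EvaluationReport",
    "PermutationPValue",
    "roc_auc",
    "auc01",
    "permutation_pvalue",
    "evaluate",
]

Rankings = Mapping[str, Sequence[tuple[str, float]]]


@dataclass(frozen=True)
class PermutationPValue:
    empirical: float
    gaussian: float
    null_mean: float
    null_sd: float
    n_perm: int


@dataclass
class EvaluationReport:
    per_disease: dict[str, dict] = field(default_factory=dict)
    avg_auc: float = float("nan")
    avg_auc01: float = float("nan")
    p_avg_auc: PermutationPValue | None = None
    p_avg_auc01: PermutationPValue | None = None

    def to_dict(self) -> dict:
        out = {
            "avg_auc": self.avg_auc,
            "avg_auc01": self.avg_auc01,
            "per_disease": self.per_disease,
        }
        for key, p in (("p_avg_auc", self.p_avg_auc), ("p_avg_auc01", self.p_avg_auc01)):
            if p is not None:
                out[key] = {"empirical": p.empirical, "gaussian": p.gaussian,
                            "null_mean": p.null_mean, "null_sd": p.null_sd}
        return out


def _check_labels(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative label")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC AUC as the Mann–Whitney probability, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_labels(labels)
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum = ranks[labels].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc01(scores: Sequence[float], labels: Sequence[bool], fpr_max: float = 0.1) -> float:
    """Unnormalized partial ROC area over FPR in [0, fpr_max].

    The ROC is interpolated linearly at the FPR = fpr_max boundary; a
    perfect ranking scores fpr_max, an uninformative one fpr_max**2 / 2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_labels(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    if fpr_max < fpr[-1]:
        tpr_at = float(np.interp(fpr_max, fpr, tpr))
        keep = fpr <= fpr_max
        fpr = np.append(fpr[keep], fpr_max)
        tpr = np.append(tpr[keep], tpr_at)
    return float(np.trapezoid(tpr, fpr))


def _disease_metrics(
    ranking: Sequence[tuple[str, float]], positives: frozenset[str]
) -> dict | None:
    drugs = [d for d, _ in ranking]
    scores = np.array([s for _, s in ranking], dtype=float)
    labels = np.array([d in positives for d in drugs])
    if labels.all() or not labels.any():
        return None
    return {
        "auc": roc_auc(scores, labels),
        "auc01": auc01(scores, labels),
        "n_pos": int(labels.sum()),
        "n_neg": int((~labels).sum()),
    }


def evaluate(
    rankings: Rankings,
    standard: BenchmarkStandard,
    n_perm: int = 0,
    rng_seed: int = 0,
) -> EvaluationReport:
    """Per-disease and averaged AUC / AUC0.1 for scored drug rankings.

    Positives for a disease are the standard's pairs; negatives are every
    other ranked candidate drug.  Diseases with no positive (or no
    negative) among their candidates are excluded with a warning.
    Averages are unweighted means over the retained diseases.  With
    ``n_perm`` > 0, permutation p-values for both averages are attached.
    """
    report = EvaluationReport()
    for disease, ranking in rankings.items():
        metrics = _disease_metrics(ranking, standard.positives_for(disease))
        if metrics is None:
            warnings.warn(f"disease {disease!r} has a single label class; excluded",
                          stacklevel=2)
            continue
        report.per_disease[disease] = metrics
    if not report.per_disease:
        raise ValueError("no disease with both positive and negative candidates")
    report.avg_auc = float(np.mean([m["auc"] for m in report.per_disease.values()]))
    report.avg_auc01 = float(np.mean([m["auc01"] for m in report.per_disease.values()]))
    if n_perm > 0:
        report.p_avg_auc = permutation_pvalue(
            rankings, standard, metric="auc", n_perm=n_perm, rng_seed=rng_seed
        )
        report.p_avg_auc01 = permutation_pvalue(
            rankings, standard, metric="auc01", n_perm=n_perm, rng_seed=rng_seed + 1
        )
    return report


def permutation_pvalue(
    rankings: Rankings,
    standard: BenchmarkStandard,
    metric: str | Callable[[np.ndarray, np.ndarray], float] = "auc",
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> PermutationPValue:
    """Permutation p-value for the cross-disease average of a ROC metric.

    The null reassigns each disease's positives uniformly at random among
    its candidate drugs, preserving per-disease positive counts, and
    recomputes the averaged metric.  Empirical p uses the +1 pseudo-count
    (never exactly 0); the Gaussian p is the upper-tail normal probability
    at the null's mean and standard deviation, which is how tail
    probabilities far below 1/n_perm arise.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    metric_fn: Callable[[np.ndarray, np.ndarray], float]
    if metric == "auc":
        metric_fn = roc_auc
    elif metric == "auc01":
        metric_fn = auc01
    elif callable(metric):
        metric_fn = metric
    else:
        raise ValueError(f"unknown metric {metric!r}")

    per_disease: list[tuple[np.ndarray, int]] = []
    observed_vals = []
    for disease, ranking in rankings.items():
        scores = np.array([s for _, s in ranking], dtype=float)
        labels = np.array([d in standard.positives_for(disease) for d, _ in ranking])
        if labels.all() or not labels.any():
            continue
        observed_vals.append(metric_fn(scores, labels))
        per_disease.append((scores, int(labels.sum())))
    if not per_disease:
        raise ValueError("no disease usable for permutation test")
    observed = float(np.mean(observed_vals))

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        vals = []
        for scores, n_pos in per_disease:
            perm_labels = np.zeros(scores.size, dtype=bool)
            perm_labels[rng.choice(scores.size, size=n_pos, replace=False)] = True
            vals.append(metric_fn(scores, perm_labels))
        null[b] = np.mean(vals)
    empirical = (1 + int((null >= observed).sum())) / (1 + n_perm)
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    gaussian = float(stats.norm.sf(observed, loc=mean, scale=sd)) if sd and sd > 0 else float("nan")
    return PermutationPValue(
        empirical=empirical, gaussian=gaussian, null_mean=mean, null_sd=sd, n_perm=n_perm
    )
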