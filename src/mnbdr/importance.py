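"""Gene-to-module feature transform via the Imp statistic.

A module's importance under a condition summarizes how strongly its genes
are perturbed: when the module's signed scores straddle zero the statistic
is the full range Fmax - Fmin, otherwise the largest absolute score.  The
same transform serves disease fold-change vectors and drug z-score
vectors, so both sides of the repositioning comparison live in the same
module feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneScoreVector, ModuleSet

__all__ = ["ImportanceVector", "fold_changes", "module_importance", "pass_all_filter",
           "filter_conditions"]


def pass_all_filter(vector: GeneScoreVector) -> bool:
    """Default condition filter: keep every score vector."""
    return True


def filter_conditions(vectors, predicate=pass_all_filter):
    """Apply a quality predicate to a mapping of condition score vectors.

    Hook for upstream sample filtering (e.g. discarding drug signatures
    with weak expression signal strength); the default keeps everything.
    """
    return {name: v for name, v in vectors.items() if predicate(v)}


@dataclass
class ImportanceVector:
    """Per-module nonnegative importance scores for one condition."""

    values: pd.Series  # index: module names, in ModuleSet order
    condition_id: str
    stage: str = "raw"  # "raw" | "propagated"

    def __post_init__(self) -> None:
        v = pd.Series(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("importance values must be nonnegative")
        self.values = v


def fold_changes(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    condition_id: str = "disease",
) -> GeneScoreVector:
    """Per-gene log2 fold change of mean case over mean control expression.

    F = log2((mean_case + pseudocount) / (mean_control + pseudocount)).
    Matrices are genes x samples with identical gene sets and nonnegative
    entries.  Fewer than 3 samples on either side triggers a warning (small
    groups give unstable means) but not an error.
    """
    import warnings

    if set(case_matrix.index) != set(control_matrix.index):
        raise ValueError("case and control matrices must share the same gene set")
    if (case_matrix.values < 0).any() or (control_matrix.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    if case_matrix.shape[1] < 3 or control_matrix.shape[1] < 3:
        warnings.warn("fewer than 3 samples in a group; fold changes may be unstable",
                      stacklevel=2)
    control_matrix = control_matrix.loc[case_matrix.index]
    mean_case = case_matrix.mean(axis=1) + pseudocount
    mean_control = control_matrix.mean(axis=1) + pseudocount
    fc = np.log2(mean_case / mean_control)
    return GeneScoreVector(scores=fc, condition_id=condition_id, condition_kind="disease")


def module_importance(scores: GeneScoreVector, modules: ModuleSet) -> ImportanceVector:
    """Map a gene score vector into module space.

    For each module, over its genes present in the score vector:
    Imp = Fmax - Fmin if Fmax > 0 and Fmin < 0, else max(|Fmax|, |Fmin|).
    Genes absent from the vector are ignored; a module with no measured
    gene scores 0, keeping the vector's length fixed for propagation.
    """
    if len(modules) == 0:
        raise ValueError("need at least one module")
    s = scores.scores
    values = {}
    for name, members in modules.items():
        present = s.reindex(list(members)).dropna()
        if present.empty:
            values[name] = 0.0
            continue
        fmax, fmin = present.max(), present.min()
        if fmax > 0 and fmin < 0:
            values[name] = fmax - fmin
        else:
            values[name] = max(abs(fmax), abs(fmin))
    return ImportanceVector(
        values=pd.Series(values, index=modules.names(), dtype=float),
        condition_id=scores.condition_id,
        stage="raw",
    )
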