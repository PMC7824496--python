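"""Rank-alignment drug–disease scoring.

Inspired by normalized discounted cumulative gain: a drug scores highly
for a disease when the disease's top modules are both strongly perturbed
by the drug and positionally near the top of the drug's own module
ranking,

    S = sum_{i=1..n} V(i) / (|P(i) - i| + 1)

where i runs over the disease's top-n modules, V(i) is the drug-side raw
importance of the disease's i-th module, and P(i) is that module's
position in the drug's full module ranking (importance descending, ties
broken lexicographically).  Note these are perturbation-overlap semantics:
the direction of the drug's effect is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .importance import ImportanceVector

__all__ = ["DrugDiseaseScore", "alignment_score", "drug_disease_score", "rank_drugs"]


def alignment_score(v: Sequence[float], positions: Sequence[int]) -> float:
    """The rank-alignment sum S = sum_i v[i] / (|positions[i] - i| + 1).

    ``v[i]`` is the drug-side importance of the disease's (i+1)-th module
    and ``positions[i]`` its 1-based position in the drug's module
    ranking.  Exposed separately so the discounting arithmetic can be
    checked independently of how positions are derived.
    """
    if len(v) != len(positions):
        raise ValueError("v and positions must have equal length")
    return float(sum(vi / (abs(pi - i) + 1)
                     for i, (vi, pi) in enumerate(zip(v, positions), start=1)))


@dataclass(frozen=True)
class DrugDiseaseScore:
    drug_id: str
    disease_id: str
    s: float
    n_used: int


def _drug_positions(drug_imp: ImportanceVector) -> dict[str, int]:
    """1-based position of every module in the drug's ranking."""
    ordered = sorted(drug_imp.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return {name: i for i, (name, _) in enumerate(ordered, start=1)}


def drug_disease_score(
    disease_top: Sequence[tuple[str, float]] | Sequence[str],
    drug_imp: ImportanceVector,
    disease_id: str = "disease",
) -> DrugDiseaseScore:
    """Score one drug against a disease's ordered top modules.

    ``disease_top`` is the disease's ranked top-n module list (names, or
    (name, score) pairs whose scores are ignored).  The drug's importance
    vector must cover every module so positions are well-defined.
    """
    names = [m[0] if isinstance(m, tuple) else m for m in disease_top]
    if not names:
        raise ValueError("disease_top must be nonempty")
    missing = [m for m in names if m not in drug_imp.values.index]
    if missing:
        raise ValueError(f"modules absent from drug importance vector: {missing[:5]}")
    positions = _drug_positions(drug_imp)
    s = alignment_score([float(drug_imp.values[m]) for m in names],
                        [positions[m] for m in names])
    return DrugDiseaseScore(
        drug_id=drug_imp.condition_id, disease_id=disease_id, s=s, n_used=len(names)
    )


def rank_drugs(
    disease_top: Sequence[tuple[str, float]] | Sequence[str],
    drug_imps: Iterable[ImportanceVector],
    disease_id: str = "disease",
) -> list[DrugDiseaseScore]:
    """Rank all drugs for one disease by S descending (ties: drug id)."""
    scored = [drug_disease_score(disease_top, imp, disease_id=disease_id) for imp in drug_imps]
    if not scored:
        raise ValueError("need at least one drug")
    return sorted(scored, key=lambda d: (-d.s, d.drug_id))
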