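"""Readers and writers for the text formats the pipeline consumes.

Interaction networks arrive as STRING-style edge lists (two node columns
plus an integer confidence in [0, 1000]); gene sets travel as GMT; score
vectors and benchmark standards are plain two-column TSV.  Gene and drug
identifiers are opaque strings throughout — callers are responsible for
harmonizing identifier spaces between the network and the expression data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclass
class ModuleSet:
    """Ordered, named gene sets (dense network modules).

    Insertion order is meaningful: modules are conventionally named
    ``M1, M2, ...`` in decreasing seed-weight order by the detector.
    """

    modules: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[str]:
        return iter(self.modules)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.modules[name]

    def __contains__(self, name: str) -> bool:
        return name in self.modules

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return self.modules == other.modules

    def items(self):
        return self.modules.items()

    def names(self) -> list[str]:
        return list(self.modules)

    def genes(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for members in self.modules.values():
            out |= members
        return frozenset(out)


@dataclass(frozen=True)
class BenchmarkStandard:
    """Known drug–disease associations used as evaluation positives.

    ``drug_universe`` is the set of drugs eligible for ranking; every
    drug occurring in ``pairs`` belongs to it.
    """

    pairs: frozenset[tuple[str, str]]
    drug_universe: frozenset[str]

    def __post_init__(self) -> None:
        missing = {d for d, _ in self.pairs} - self.drug_universe
        if missing:
            raise ValueError(
                f"benchmark pairs reference drugs outside the universe: {sorted(missing)[:5]}"
            )

    def positives_for(self, disease_id: str) -> frozenset[str]:
        return frozenset(d for d, dis in self.pairs if dis == disease_id)

    def diseases(self) -> frozenset[str]:
        return frozenset(dis for _, dis in self.pairs)


@dataclass
class GeneScoreVector:
    """Signed per-gene perturbation values for one condition.

    Disease vectors hold log fold-changes; drug vectors hold perturbation
    z-scores.  Both feed the same module-importance transform.
    """

    scores: pd.Series
    condition_id: str
    condition_kind: str = "disease"  # "disease" | "drug"

    def __post_init__(self) -> None:
        s = pd.Series(self.scores, dtype=float)
        if not s.map(lambda v: v == v and abs(v) != float("inf")).all():
            raise ValueError(f"non-finite score in condition {self.condition_id!r}")
        self.scores = s


def read_ppi(path: str | Path, min_confidence: int = 770) -> nx.Graph:
    """Read a STRING-style edge list, keeping edges scoring >= *min_confidence*.

    The file is whitespace/tab delimited with at least three columns
    (node, node, integer confidence).  A header line is tolerated and
    auto-detected by a non-numeric third field.  Edges are deduplicated as
    unordered pairs (the maximum confidence wins on conflict), self-loops
    are dropped, and nodes left without any retained edge do not appear.
    """
    if not 0 <= min_confidence <= 1000:
        raise ValueError("min_confidence must be in [0, 1000]")
    graph = nx.Graph()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                score = int(float(raw))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric confidence {raw!r}") from None
            if a == b or score < min_confidence:
                continue
            prev = graph.get_edge_data(a, b)
            if prev is None or prev["confidence"] < score:
                graph.add_edge(a, b, confidence=score)
    if graph.number_of_edges() == 0:
        warnings.warn(
            f"no interactions with confidence >= {min_confidence} in {path}",
            stacklevel=2,
        )
    return graph


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    """Write an interaction graph back to a three-column edge list."""
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('confidence', 1000)}\n")


def read_modules(path: str | Path) -> ModuleSet:
    """Read a GMT file (name, description, tab-separated members)."""
    modules: dict[str, frozenset[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = fields[0]
            if name in modules:
                raise ParseError(f"{path}:{lineno}: duplicate module name {name!r}")
            modules[name] = frozenset(g for g in fields[2:] if g)
    return ModuleSet(modules)


def write_modules(modules: ModuleSet, path: str | Path, description: str = "na") -> None:
    if len(set(modules.names())) != len(modules):
        raise ValueError("module names must be unique")
    with Path(path).open("w") as fh:
        for name, members in modules.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_benchmark(path: str | Path) -> BenchmarkStandard:
    """Read a two-column (drug_id, disease_id) TSV of known associations."""
    pairs: set[tuple[str, str]] = set()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pairs.add((fields[0], fields[1]))
    return BenchmarkStandard(
        pairs=frozenset(pairs), drug_universe=frozenset(d for d, _ in pairs)
    )


def write_benchmark(standard: BenchmarkStandard, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for drug, disease in sorted(standard.pairs):
            fh.write(f"{drug}\t{disease}\n")


def read_gene_scores(
    path: str | Path, condition_id: str | None = None, condition_kind: str = "disease"
) -> GeneScoreVector:
    """Read a two-column (gene_id, value) TSV into a score vector."""
    path = Path(path)
    values: dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                values[fields[0]] = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric value {fields[1]!r}") from None
    return GeneScoreVector(
        scores=pd.Series(values, dtype=float),
        condition_id=condition_id or path.stem,
        condition_kind=condition_kind,
    )


def write_gene_scores(vector: GeneScoreVector, path: str | Path) -> None:
    vector.scores.sort_index().to_csv(path, sep="\t", header=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (gene rows, header of sample ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)
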