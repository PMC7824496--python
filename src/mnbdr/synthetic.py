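"""Seeded synthetic benchmarks for the full repositioning pipeline.

The generator emulates the three real inputs the method consumes, at desk
scale: a sparse interaction network with planted dense modules (cliques)
and planted cross-talk enrichment between designated module pairs;
disease score vectors in which a disease's driver modules carry large
mixed-sign perturbations; and drug score vectors in which true drugs
perturb the disease's driver modules while decoys perturb unrelated
module pairs or pure noise.  Every generator is a pure function of its
seed and parameters.

Default regime (sized for a single CPU in minutes): 12 planted modules of
8 genes, 6 disjoint cross-talk pairs with bipartite edge probability
0.3, 600 background genes with Erdős–Rényi edge probability 0.005,
10 diseases, 60 drugs, 6 true drugs per disease, effect size 2.5, noise
standard deviation 0.8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    BenchmarkStandard,
    GeneScoreVector,
    ModuleSet,
    write_benchmark,
    write_gene_scores,
    write_modules,
    write_ppi,
)

__all__ = [
    "SyntheticTruth",
    "simulate_ppi",
    "simulate_condition_scores",
    "simulate_benchmark",
    "write_fixture_dir",
]

import pandas as pd


@dataclass
class SyntheticTruth:
    """Ground truth for a generated benchmark."""

    planted_modules: ModuleSet
    planted_crosstalk_pairs: list[tuple[str, str]]
    disease_driver_modules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    true_drugs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.params["gene_universe"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_modules": {k: sorted(v) for k, v in self.planted_modules.items()},
                "planted_crosstalk_pairs": self.planted_crosstalk_pairs,
                "disease_driver_modules": {k: list(v) for k, v in
                                           self.disease_driver_modules.items()},
                "true_drugs": {k: list(v) for k, v in self.true_drugs.items()},
                "params": self.params,
            },
            indent=1,
        )


def simulate_ppi(
    n_modules: int = 12,
    module_size: int = 8,
    n_crosstalk_pairs: int = 6,
    crosstalk_edge_prob: float = 0.3,
    n_background_genes: int = 600,
    background_edge_prob: float = 0.005,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Plant disjoint cliques and cross-talk enrichment in a sparse graph.

    Cross-talk pairs form a disjoint matching over the first
    ``2 * n_crosstalk_pairs`` planted modules; each designated pair gets
    Bernoulli(``crosstalk_edge_prob``) bipartite edges.  An Erdős–Rényi
    background with edge probability ``background_edge_prob`` spans the
    whole gene universe.  All edges carry confidence 999.
    """
    if module_size < 5:
        raise ValueError("module_size must be >= 5 (minimum retained cluster size)")
    if 2 * n_crosstalk_pairs > n_modules:
        raise ValueError("cross-talk pairs must be disjoint: need n_modules >= 2 * pairs")
    rng = np.random.default_rng(seed)

    module_genes = {
        f"P{i + 1:02d}": [f"p{i + 1:02d}g{j + 1}" for j in range(module_size)]
        for i in range(n_modules)
    }
    background = [f"bg{j + 1:04d}" for j in range(n_background_genes)]
    universe = [g for genes in module_genes.values() for g in genes] + background

    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for genes in module_genes.values():
        for i, u in enumerate(genes):
            for v in genes[i + 1:]:
                graph.add_edge(u, v, confidence=999)

    names = list(module_genes)
    pairs = [(names[2 * i], names[2 * i + 1]) for i in range(n_crosstalk_pairs)]
    for a, b in pairs:
        for u in module_genes[a]:
            for v in module_genes[b]:
                if rng.random() < crosstalk_edge_prob:
                    graph.add_edge(u, v, confidence=999)

    n = len(universe)
    if background_edge_prob > 0:
        # vectorized Bernoulli over all upper-triangle pairs; pairs with both
        # endpoints inside planted modules are excluded so inter-module
        # connectivity is governed solely by crosstalk_edge_prob and the
        # detection ground truth stays unambiguous
        planted = {g for genes in module_genes.values() for g in genes}
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < background_edge_prob
        arr = np.asarray(universe, dtype=object)
        for u, v in zip(arr[iu[mask]], arr[ju[mask]]):
            if u in planted and v in planted:
                continue
            if not graph.has_edge(u, v):
                graph.add_edge(u, v, confidence=999)

    truth = SyntheticTruth(
        planted_modules=ModuleSet({k: frozenset(v) for k, v in module_genes.items()}),
        planted_crosstalk_pairs=pairs,
        params={
            "n_modules": n_modules,
            "module_size": module_size,
            "n_crosstalk_pairs": n_crosstalk_pairs,
            "crosstalk_edge_prob": crosstalk_edge_prob,
            "n_background_genes": n_background_genes,
            "background_edge_prob": background_edge_prob,
            "seed": seed,
            "gene_universe": universe,
        },
    )
    return graph, truth


def simulate_condition_scores(
    truth: SyntheticTruth,
    condition_kind: str,
    driver_modules: tuple[str, ...] | list[str],
    effect_size: float = 2.5,
    noise_sd: float = 0.8,
    seed: int = 0,
    condition_id: str | None = None,
) -> GeneScoreVector:
    """Signed gene scores with planted signal in the driver modules.

    Driver-module genes draw from ±effect_size + Normal(0, noise_sd) with
    an enforced mix of signs inside each module (half positive, half
    negative, positions shuffled), so the straddle branch of the module
    importance statistic is always exercised.  All other genes draw pure
    Normal(0, noise_sd) noise.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    values = pd.Series(rng.normal(0.0, noise_sd, size=len(genes)), index=genes)
    for module in driver_modules:
        members = sorted(truth.planted_modules[module])
        signs = np.ones(len(members))
        signs[len(members) // 2:] = -1.0
        rng.shuffle(signs)
        values.loc[members] = signs * effect_size + rng.normal(0.0, noise_sd, len(members))
    return GeneScoreVector(
        scores=values,
        condition_id=condition_id or f"{condition_kind}_{'_'.join(driver_modules) or 'null'}",
        condition_kind=condition_kind,
    )


def simulate_benchmark(
    truth: SyntheticTruth,
    n_diseases: int = 10,
    n_drugs: int = 60,
    n_true_per_disease: int = 6,
    effect_size: float = 2.5,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, GeneScoreVector], dict[str, GeneScoreVector], BenchmarkStandard]:
    """Generate disease vectors, drug vectors, and the benchmark standard.

    Each disease is driven by one planted cross-talk pair (pairs recycle
    round-robin when diseases outnumber pairs, so diseases sharing a pair
    share true drugs).  For every used pair, ``n_true_per_disease`` true
    drugs perturb exactly that pair's modules.  Remaining drugs are
    decoys: half perturb a random module pair that is NOT a planted
    cross-talk pair, half are pure noise.  The standard pairs a disease
    with every drug targeting its driver pair.  Driver assignments and
    true-drug sets are recorded on ``truth``.
    """
    if not truth.planted_crosstalk_pairs:
        raise ValueError("benchmark generation needs planted cross-talk pairs")
    pairs = truth.planted_crosstalk_pairs
    used_pairs = sorted({pairs[i % len(pairs)] for i in range(n_diseases)})
    n_targeted = len(used_pairs) * n_true_per_disease
    if n_targeted > n_drugs:
        raise ValueError(
            f"need >= {n_targeted} drugs for {len(used_pairs)} driver pairs "
            f"x {n_true_per_disease} true drugs"
        )
    root = np.random.default_rng(seed)
    module_names = truth.planted_modules.names()

    diseases: dict[str, GeneScoreVector] = {}
    disease_pair: dict[str, tuple[str, str]] = {}
    for i in range(n_diseases):
        name = f"D{i + 1:02d}"
        pair = pairs[i % len(pairs)]
        disease_pair[name] = pair
        diseases[name] = simulate_condition_scores(
            truth, "disease", pair, effect_size, noise_sd,
            seed=int(root.integers(2**31)), condition_id=name,
        )
        truth.disease_driver_modules[name] = pair

    drugs: dict[str, GeneScoreVector] = {}
    drug_pair: dict[str, tuple[str, str] | None] = {}
    counter = 0
    for pair in used_pairs:
        for _ in range(n_true_per_disease):
            name = f"R{counter + 1:03d}"
            counter += 1
            drugs[name] = simulate_condition_scores(
                truth, "drug", pair, effect_size, noise_sd,
                seed=int(root.integers(2**31)), condition_id=name,
            )
            drug_pair[name] = pair
    crosstalk_set = {frozenset(p) for p in pairs}
    n_decoys = n_drugs - counter
    for k in range(n_decoys):
        name = f"R{counter + 1:03d}"
        counter += 1
        if k % 2 == 0 and len(module_names) >= 2:
            # off-target decoy: perturbs a module pair with no planted cross-talk
            while True:
                pick = tuple(sorted(root.choice(module_names, size=2, replace=False)))
                if frozenset(pick) not in crosstalk_set:
                    break
            targets: tuple[str, ...] = pick
        else:
            targets = ()
        drugs[name] = simulate_condition_scores(
            truth, "drug", targets, effect_size, noise_sd,
            seed=int(root.integers(2**31)), condition_id=name,
        )
        drug_pair[name] = None

    positives = {
        (drug, disease)
        for disease, dpair in disease_pair.items()
        for drug, rpair in drug_pair.items()
        if rpair == dpair
    }
    for disease in diseases:
        truth.true_drugs[disease] = tuple(
            sorted(d for d, dis in positives if dis == disease)
        )
    standard = BenchmarkStandard(
        pairs=frozenset(positives), drug_universe=frozenset(drugs)
    )
    return diseases, drugs, standard


def write_fixture_dir(
    out_dir: str | Path,
    graph: nx.Graph,
    truth: SyntheticTruth,
    diseases: dict[str, GeneScoreVector],
    drugs: dict[str, GeneScoreVector],
    standard: BenchmarkStandard,
) -> None:
    """Write a full synthetic benchmark as plain-text files."""
    out = Path(out_dir)
    (out / "diseases").mkdir(parents=True, exist_ok=True)
    (out / "drugs").mkdir(exist_ok=True)
    write_ppi(graph, out / "ppi.tsv")
    write_modules(truth.planted_modules, out / "modules-truth.gmt")
    for name, vec in diseases.items():
        write_gene_scores(vec, out / "diseases" / f"{name}.tsv")
    for name, vec in drugs.items():
        write_gene_scores(vec, out / "drugs" / f"{name}.tsv")
    write_benchmark(standard, out / "benchmark.tsv")
    (out / "truth.json").write_text(truth.to_json())
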